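"""Reading PSI-MITAB 2.5 interaction evidence.

Each MITAB row describes one protein-protein interaction record: the two
interactors, the experimental detection method(s) as PSI-MI controlled
vocabulary accessions (``MI:NNNN``), and the source database. Only the
first 15 columns of the 2.5 layout are used; the confidence column is
ignored because reliability weights are recomputed downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import yaml

logger = logging.getLogger(__name__)

MI_ACCESSION = re.compile(r"MI:\d{4}")
_TAXID = re.compile(r"taxid:(-?\d+)")
_PAREN_LABEL = re.compile(r"\(([^)]*)\)")

#: Minimum number of tab-separated columns for a valid MITAB 2.5 row.
MITAB_MIN_COLUMNS = 15


@dataclass(frozen=True)
class InteractionRecord:
    """One parsed MITAB row, in either raw-protein or gene identifier space."""

    interactor_a: str
    interactor_b: str
    methods: frozenset[str]
    source: str = ""
    taxon_a: str | None = None
    taxon_b: str | None = None


@dataclass(frozen=True)
class MethodWhitelist:
    """PSI-MI detection-method accessions accepted as reliable experimental
    validation.

    The shipped default covers the common experimental families
    (two-hybrid, coimmunoprecipitation, affinity chromatography,
    cross-linking, X-ray crystallography, NMR, pull-down, FRET, surface
    plasmon resonance). It is a documented stand-in that users should
    override to match their own curation policy; all pipeline logic is
    whitelist-agnostic.
    """

    accepted: frozenset[str]

    def __post_init__(self) -> None:
        if not self.accepted:
            raise ValueError("method whitelist must be non-empty")
        bad = [m for m in self.accepted if not MI_ACCESSION.fullmatch(m)]
        if bad:
            raise ValueError(f"not PSI-MI accessions: {sorted(bad)}")

    def __contains__(self, accession: str) -> bool:
        return accession in self.accepted

    @classmethod
    def load(cls, path: str | Path) -> "MethodWhitelist":
        """Load a whitelist from YAML (list or ``accepted:`` key) or from a
        one-accession-per-line text/TSV file (first column)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            data = yaml.safe_load(text)
            items = data["accepted"] if isinstance(data, dict) else data
        else:
            items = [
                line.split("\t")[0].strip()
                for line in text.splitlines()
                if line.strip() and not line.startswith("#")
            ]
        return cls(accepted=frozenset(items))

    @classmethod
    def default(cls) -> "MethodWhitelist":
        with resources.files("ppinet.data").joinpath("method_whitelist.yaml").open() as fh:
            return cls(accepted=frozenset(yaml.safe_load(fh)["accepted"]))


@dataclass
class IdMap:
    """Multimap from raw interactor identifiers to gene identifiers.

    A raw protein identifier may map to several gene identifiers; records
    touching such an interactor are multiplied over the alternatives.
    Unmappable identifiers are dropped with an explicit count, never
    silently.
    """

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __getitem__(self, raw_id: str) -> tuple[str, ...]:
        return self.entries.get(raw_id, ())

    def __contains__(self, raw_id: str) -> bool:
        return raw_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IdMap":
        entries: dict[str, list[str]] = {}
        for raw, gene in pairs:
            bucket = entries.setdefault(raw, [])
            if gene not in bucket:
                bucket.append(gene)
        return cls(entries={k: tuple(sorted(v)) for k, v in entries.items()})

    @classmethod
    def load(cls, path: str | Path) -> "IdMap":
        """Load a 2-column TSV (raw_id, gene_id), one row per mapping."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"identifier map row needs 2 columns: {line!r}")
            pairs.append((cols[0], cols[1]))
        return cls.from_pairs(pairs)


def _strip_db_prefix(identifier: str) -> str:
    """``uniprotkb:P04637`` -> ``P04637``; bare IDs pass through."""
    head = identifier.split("|", 1)[0]
    if ":" in head:
        return head.split(":", 1)[1].strip('"')
    return head


def _parse_taxon(field_text: str) -> str | None:
    m = _TAXID.search(field_text)
    return m.group(1) if m else None


def _parse_source(field_text: str) -> str:
    """Source database label from column 13: prefer the human-readable name
    in parentheses, fall back to the MI accession, then the raw text."""
    m = _PAREN_LABEL.search(field_text)
    if m and m.group(1):
        return m.group(1)
    m = MI_ACCESSION.search(field_text)
    if m:
        return m.group(0)
    return field_text.strip() if field_text.strip() != "-" else ""


def parse_mitab(
    stream: TextIO | Iterable[str],
    source: str | None = None,
) -> tuple[list[InteractionRecord], int]:
    """Parse PSI-MITAB 2.5 lines into interaction records.

    Parameters
    ----------
    stream
        Iterable of tab-delimited lines. Header lines starting with ``#``
        are ignored.
    source
        Optional source-database label overriding column 13 (useful when a
        whole file comes from one database).

    Returns
    -------
    (records, n_skipped)
        One record per well-formed row; ``n_skipped`` counts rows dropped
        for having fewer than 15 columns or no parseable PSI-MI method
        accession. Skips are also logged.
    """
    records: list[InteractionRecord] = []
    n_skipped = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < MITAB_MIN_COLUMNS:
            n_skipped += 1
            logger.warning("line %d: %d columns (< %d), skipped",
                           lineno, len(cols), MITAB_MIN_COLUMNS)
            continue
        methods = frozenset(MI_ACCESSION.findall(cols[6]))
        if not methods:
            n_skipped += 1
            logger.warning(
                "line %d: no PSI-MI accession in method field %r, skipped",
                lineno, cols[6])
            continue
        records.append(InteractionRecord(
            interactor_a=_strip_db_prefix(cols[0]),
            interactor_b=_strip_db_prefix(cols[1]),
            methods=methods,
            source=source if source is not None else _parse_source(cols[12]),
            taxon_a=_parse_taxon(cols[9]),
            taxon_b=_parse_taxon(cols[10]),
        ))
    if n_skipped:
        logger.info("parse_mitab: %d rows skipped, %d records kept",
                    n_skipped, len(records))
    return records, n_skipped


def parse_mitab_file(path: str | Path, source: str | None = None
                     ) -> tuple[list[InteractionRecord], int]:
    with open(path) as fh:
        return parse_mitab(fh, source=source)


def write_mitab(records: Sequence[InteractionRecord]) -> Iterator[str]:
    """Serialize records back to minimal MITAB 2.5 lines.

    Only the fields this pipeline retains are populated (interactors,
    methods, taxa, source database); the other columns hold ``-``.
    A parse of the output reproduces the records exactly.
    """
    for rec in records:
        cols = ["-"] * MITAB_MIN_COLUMNS
        cols[0] = f"unknown:{rec.interactor_a}"
        cols[1] = f"unknown:{rec.interactor_b}"
        cols[6] = "|".join(
            f'psi-mi:"{m}"(unspecified)' for m in sorted(rec.methods))
        if rec.taxon_a is not None:
            cols[9] = f"taxid:{rec.taxon_a}"
        if rec.taxon_b is not None:
            cols[10] = f"taxid:{rec.taxon_b}"
        if rec.source:
            cols[12] = f"psi-mi:\"MI:0000\"({rec.source})"
        yield "\t".join(cols)


def filter_experimental(
    records: Iterable[InteractionRecord],
    whitelist: MethodWhitelist,
) -> tuple[list[InteractionRecord], int]:
    """Keep records carrying at least one whitelisted experimental method.

    A record is kept iff its method set intersects the whitelist; kept
    records have their method set reduced to the whitelisted subset, so
    non-experimental evidence never propagates downstream.

    Returns ``(kept_records, n_discarded)``.
    """
    kept: list[InteractionRecord] = []
    n_discarded = 0
    for rec in records:
        retained = rec.methods & whitelist.accepted
        if retained:
            kept.append(rec if retained == rec.methods
                        else replace(rec, methods=frozenset(retained)))
        else:
            n_discarded += 1
    if n_discarded:
        logger.info("filter_experimental: %d records discarded", n_discarded)
    return kept, n_discarded


def filter_intra_species(
    records: Iterable[InteractionRecord],
) -> tuple[list[InteractionRecord], int]:
    """Optionally reject cross-species records (both taxa present and
    different). Off the main path by default: organism selection normally
    happens upstream, when the MITAB files are exported.

    Records with a missing taxon on either side are kept.

    Returns ``(kept_records, n_discarded)``.
    """
    kept: list[InteractionRecord] = []
    n_discarded = 0
    for rec in records:
        if rec.taxon_a is not None and rec.taxon_b is not None \
                and rec.taxon_a != rec.taxon_b:
            n_discarded += 1
        else:
            kept.append(rec)
    if n_discarded:
        logger.info("filter_intra_species: %d cross-species records "
                    "discarded", n_discarded)
    return kept, n_discarded


def map_identifiers(
    records: Iterable[InteractionRecord],
    idmap: IdMap,
) -> tuple[list[InteractionRecord], int]:
    """Convert records from raw protein identifiers to gene identifiers.

    An interactor mapping to several genes multiplies the record over the
    cross-product of the alternatives. Records with an unmappable
    interactor are dropped and counted.

    Returns ``(mapped_records, n_dropped)``.
    """
    mapped: list[InteractionRecord] = []
    n_dropped = 0
    for rec in records:
        genes_a = idmap[rec.interactor_a]
        genes_b = idmap[rec.interactor_b]
        if not genes_a or not genes_b:
            n_dropped += 1
            continue
        for ga in genes_a:
            for gb in genes_b:
                mapped.append(replace(rec, interactor_a=ga, interactor_b=gb))
    if n_dropped:
        logger.info("map_identifiers: %d records dropped (unmappable)",
                    n_dropped)
    return mapped, n_dropped
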