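"""Cross-link identification reports: parsing, filtering, deduplication.

Search engines such as pLink emit one row per identified spectrum.  The
same lysine pair is typically supported by many spectra and may be written
in either residue order, so downstream analyses work on *non-redundant*
site pairs: the canonical unordered pair of (protein accession, residue
number) with a spectral count, the best E-value seen, and an
intra/inter/ambiguous classification.

Filtering follows the usual two-stage convention: spectrum-level thresholds
(FDR, E-value) are applied to rows; the spectral-count floor applies after
deduplication, at the pair level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .chem import Channel, LinkType

__all__ = [
    "SpectrumMatch",
    "LinkPair",
    "FilterConfig",
    "ReportDialect",
    "parse_report",
    "write_report",
    "filter_matches",
    "deduplicate",
    "classify_pair",
    "classify_pairs",
    "merge_datasets",
    "MergeResult",
    "write_pair_table",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SpectrumMatch:
    """One identified spectrum from a search report.

    ``proteins_a``/``proteins_b`` are tuples because a peptide can map to
    several database entries; the first accession is the representative
    used for pair identity.
    """

    spectrum_id: str
    link_type: LinkType
    proteins_a: tuple[str, ...]
    site_a: int
    proteins_b: tuple[str, ...] = ()
    site_b: Optional[int] = None
    peptide_a: str = ""
    peptide_b: str = ""
    charge: int = 2
    e_value: float = 0.0
    fdr: float = 0.0
    channel: str = "unlabeled"
    raw_file: str = ""

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.site_a < 1 or (self.site_b is not None and self.site_b < 1):
            raise ValueError("residue numbers are 1-based")
        if self.link_type is LinkType.INTER and not self.proteins_b:
            raise ValueError("inter-link row must name both proteins")


@dataclass(frozen=True)
class LinkPair:
    """A non-redundant cross-linked site pair."""

    site_1: tuple[str, int]
    site_2: tuple[str, int]
    link_type: LinkType
    classification: str = "unclassified"   # intra | inter | ambiguous
    spectral_count: int = 1
    best_e_value: float = 0.0
    candidates_1: tuple[str, ...] = ()
    candidates_2: tuple[str, ...] = ()
    sources: tuple[str, ...] = ()
    source_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")
        if self.site_2 < self.site_1:
            raise ValueError("pair sites must be canonically ordered")

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.site_1, self.site_2)


@dataclass(frozen=True)
class FilterConfig:
    """Spectrum- and pair-level identification thresholds."""

    max_fdr: float = 0.05
    max_e_value: float = 0.01
    min_spectral_count: int = 3

    def __post_init__(self) -> None:
        if self.max_fdr < 0 or self.max_e_value < 0 or self.min_spectral_count < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class ReportDialect:
    """Column-name map and separators for a delimited report file."""

    sep: str = ","
    protein_sep: str = "/"
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "spectrum_id": "spectrum",
            "raw_file": "raw_file",
            "link_type": "link_type",
            "protein_a": "protein_a",
            "site_a": "site_a",
            "protein_b": "protein_b",
            "site_b": "site_b",
            "peptide_a": "peptide_a",
            "peptide_b": "peptide_b",
            "charge": "charge",
            "e_value": "e_value",
            "fdr": "fdr",
            "channel": "channel",
        }
    )


DEFAULT_DIALECT = ReportDialect()
_MANDATORY = ("spectrum_id", "link_type", "protein_a", "site_a", "e_value", "fdr")


def parse_report(
    path: PathLike, dialect: ReportDialect = DEFAULT_DIALECT
) -> list[SpectrumMatch]:
    """Read a delimited identification report into SpectrumMatch rows."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    cols = dialect.columns
    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise ValueError(f"report is missing mandatory column {cols[key]!r}")

    def split_proteins(cell: str) -> tuple[str, ...]:
        cell = cell.strip()
        if not cell:
            return ()
        return tuple(p for p in cell.split(dialect.protein_sep) if p)

    def num(cell: str, kind, row: int, col: str):
        try:
            return kind(cell)
        except ValueError:
            raise ValueError(
                f"unparseable value {cell!r} in column {col!r}, data row {row + 1}"
            ) from None

    matches: list[SpectrumMatch] = []
    for i, row in enumerate(df.to_dict("records")):
        def get(key: str, default: str = "") -> str:
            col = cols.get(key)
            return row.get(col, default) if col else default

        link_type = LinkType(get("link_type").strip().lower())
        site_b_cell = get("site_b").strip()
        matches.append(
            SpectrumMatch(
                spectrum_id=get("spectrum_id"),
                raw_file=get("raw_file"),
                link_type=link_type,
                proteins_a=split_proteins(get("protein_a")),
                site_a=num(get("site_a"), int, i, cols["site_a"]),
                proteins_b=split_proteins(get("protein_b")),
                site_b=num(site_b_cell, int, i, cols["site_b"]) if site_b_cell else None,
                peptide_a=get("peptide_a"),
                peptide_b=get("peptide_b"),
                charge=num(get("charge") or "2", int, i, cols.get("charge", "charge")),
                e_value=num(get("e_value"), float, i, cols["e_value"]),
                fdr=num(get("fdr"), float, i, cols["fdr"]),
                channel=get("channel") or "unlabeled",
            )
        )
    return matches


def write_report(
    matches: Iterable[SpectrumMatch],
    path: PathLike,
    dialect: ReportDialect = DEFAULT_DIALECT,
) -> None:
    cols = dialect.columns
    rows = []
    for m in matches:
        rows.append(
            {
                cols["spectrum_id"]: m.spectrum_id,
                cols["raw_file"]: m.raw_file,
                cols["link_type"]: m.link_type.value,
                cols["protein_a"]: dialect.protein_sep.join(m.proteins_a),
                cols["site_a"]: m.site_a,
                cols["protein_b"]: dialect.protein_sep.join(m.proteins_b),
                cols["site_b"]: "" if m.site_b is None else m.site_b,
                cols["peptide_a"]: m.peptide_a,
                cols["peptide_b"]: m.peptide_b,
                cols["charge"]: m.charge,
                cols["e_value"]: m.e_value,
                cols["fdr"]: m.fdr,
                cols["channel"]: m.channel,
            }
        )
    df = pd.DataFrame(rows, columns=list(cols.values()))
    df.to_csv(path, sep=dialect.sep, index=False)


def filter_matches(
    matches: Iterable[SpectrumMatch], cfg: FilterConfig = FilterConfig()
) -> list[SpectrumMatch]:
    """Spectrum-level filter: FDR < max_fdr and E-value < max_e_value.

    The spectral-count floor is a pair-level criterion; apply it via
    ``deduplicate(..., min_spectral_count=...)``.
    """
    return [
        m
        for m in matches
        if m.fdr < cfg.max_fdr and m.e_value < cfg.max_e_value
    ]


def _canonical_sites(m: SpectrumMatch):
    a = ((m.proteins_a[0], m.site_a), m.proteins_a)
    if m.link_type is LinkType.INTER:
        b = ((m.proteins_b[0], m.site_b), m.proteins_b)
    elif m.link_type is LinkType.LOOP:
        b = ((m.proteins_a[0], m.site_b), m.proteins_a)
    else:
        b = a
    return (a, b) if a[0] <= b[0] else (b, a)


def deduplicate(
    matches: Iterable[SpectrumMatch],
    source: str = "",
    min_spectral_count: int = 1,
) -> list[LinkPair]:
    """Collapse spectrum matches to canonical non-redundant site pairs.

    A pair and its site-swapped mirror are the same identity.  Loop- and
    mono-links keep their own link_type and never merge into inter-link
    identity.  Pairs below ``min_spectral_count`` supporting spectra are
    dropped (the pair-level floor).
    """
    groups: dict = {}
    for m in matches:
        (s1, cand1), (s2, cand2) = _canonical_sites(m)
        key = (m.link_type, s1, s2)
        if key not in groups:
            groups[key] = {
                "count": 0,
                "best_e": math.inf,
                "cand1": cand1,
                "cand2": cand2,
            }
        g = groups[key]
        g["count"] += 1
        g["best_e"] = min(g["best_e"], m.e_value)
    pairs = [
        LinkPair(
            site_1=s1,
            site_2=s2,
            link_type=lt,
            spectral_count=g["count"],
            best_e_value=g["best_e"],
            candidates_1=g["cand1"],
            candidates_2=g["cand2"],
            sources=(source,) if source else (),
            source_counts={source: g["count"]} if source else {},
        )
        for (lt, s1, s2), g in sorted(groups.items())
        if g["count"] >= min_spectral_count
    ]
    return pairs


def classify_pair(pair: LinkPair) -> str:
    """intra / inter / ambiguous by the multi-mapping of both sites.

    intra if both sites are uniquely assigned to the same protein, inter if
    uniquely assigned to different proteins, ambiguous whenever either
    peptide could be attributed to multiple proteins (e.g. a peptide shared
    between two near-identical paralogs) — those pairs are the ones
    conventionally rendered grey in network figures.
    """
    set1 = set(pair.candidates_1) or {pair.site_1[0]}
    set2 = set(pair.candidates_2) or {pair.site_2[0]}
    if len(set1) == 1 and len(set2) == 1:
        return "intra" if set1 == set2 else "inter"
    return "ambiguous"


def classify_pairs(pairs: Iterable[LinkPair]) -> list[LinkPair]:
    return [replace(p, classification=classify_pair(p)) for p in pairs]


@dataclass(frozen=True)
class MergeResult:
    pairs: list[LinkPair]
    set_sizes: tuple[int, ...]
    overlap_counts: Mapping[tuple[int, int], int]

    @property
    def n_union(self) -> int:
        return len(self.pairs)


def merge_datasets(pair_sets: Sequence[Sequence[LinkPair]]) -> MergeResult:
    """Non-redundant union of canonical pair sets with provenance.

    Spectral counts are summed overall but kept per source; pairwise
    overlap sizes between the input sets are reported.
    """
    merged: dict = {}
    keysets = []
    for pairs in pair_sets:
        keys = set()
        for p in pairs:
            key = (p.link_type, p.site_1, p.site_2)
            keys.add(key)
            if key not in merged:
                merged[key] = replace(p, source_counts=dict(p.source_counts))
            else:
                q = merged[key]
                counts = dict(q.source_counts)
                for src, n in p.source_counts.items():
                    counts[src] = counts.get(src, 0) + n
                merged[key] = replace(
                    q,
                    spectral_count=q.spectral_count + p.spectral_count,
                    best_e_value=min(q.best_e_value, p.best_e_value),
                    sources=tuple(dict.fromkeys(q.sources + p.sources)),
                    source_counts=counts,
                )
        keysets.append(keys)
    overlaps = {
        (i, j): len(keysets[i] & keysets[j])
        for i in range(len(keysets))
        for j in range(i + 1, len(keysets))
    }
    return MergeResult(
        pairs=[merged[k] for k in sorted(merged)],
        set_sizes=tuple(len(k) for k in keysets),
        overlap_counts=overlaps,
    )


def write_pair_table(pairs: Iterable[LinkPair], path: PathLike) -> None:
    """Write the canonical pair table as TSV."""
    rows = [
        {
            "protein_1": p.site_1[0],
            "site_1": p.site_1[1],
            "protein_2": p.site_2[0],
            "site_2": p.site_2[1],
            "type": p.link_type.value,
            "classification": p.classification,
            "spectral_count": p.spectral_count,
            "best_e_value": p.best_e_value,
            "sources": ";".join(p.sources),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
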