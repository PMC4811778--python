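"""Map cross-linked lysine pairs onto structures and score Calpha distances.

A cross-link constrains the Calpha-Calpha distance of its two residues to
roughly the linker spacer plus two lysine side chains (<=22 A for a 9.3-A
spacer) or, allowing solution-state flexibility, <=30 A.  Protein
(UniProt-style) residue numbering rarely matches structure author
numbering, so each protein sequence is globally aligned to every chain and
a per-residue map built from the alignment; multi-copy structures are
handled by minimizing the distance over all consistent chain assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gemmi
import numpy as np
from Bio import Align

from .linkio import LinkPair

__all__ = [
    "StructureModel",
    "ChainMapEntry",
    "ChainMap",
    "DistanceRecord",
    "CompatibilitySummary",
    "load_structure",
    "map_protein_to_chains",
    "build_chain_map",
    "pair_distance",
    "compatibility_summary",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class StructureModel:
    """Calpha-level view of a structure: per chain, ordered residues.

    ``chains`` maps chain id to a list of ``(residue_key, residue_name,
    ca_xyz)`` where residue_key is the author seqid plus insertion code.
    """

    chains: Mapping[str, tuple[tuple[str, str, tuple[float, float, float]], ...]]
    name: str = ""

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(
            gemmi.find_tabulated_residue(res_name).one_letter_code.upper()
            if gemmi.find_tabulated_residue(res_name) else "X"
            for _, res_name, _ in self.chains[chain_id]
        )

    def ca(self, chain_id: str, residue_key: str) -> Optional[np.ndarray]:
        for key, _, xyz in self.chains[chain_id]:
            if key == residue_key:
                return np.asarray(xyz)
        return None


def load_structure(path: PathLike) -> StructureModel:
    """Read a PDB or mmCIF file into a Calpha model.

    Alternate locations are resolved to the highest-occupancy conformer;
    insertion codes are preserved in residue keys.  Only the first model of
    multi-model files is used.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    model = st[0]
    chains: dict[str, list] = {}
    for chain in model:
        residues = []
        for residue in chain:
            cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
            if not cas:
                continue
            ca = max(cas, key=lambda a: a.occ)
            key = str(residue.seqid.num) + (residue.seqid.icode.strip() or "")
            residues.append((key, residue.name, (ca.pos.x, ca.pos.y, ca.pos.z)))
        if residues:
            chains[chain.name] = tuple(residues)
    if not chains:
        raise ValueError(f"no Calpha atoms found in {path}")
    return StructureModel(chains=chains, name=Path(path).stem)


@dataclass(frozen=True)
class ChainMapEntry:
    """One protein-to-chain alignment: residue-number map plus identity."""

    chain_id: str
    identity: float
    # protein residue number (1-based) -> structure residue key
    residue_map: Mapping[int, str]


ChainMap = Mapping[str, tuple[ChainMapEntry, ...]]


def _align_identity(seq_a: str, seq_b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # free end gaps: tolerate tags / truncated constructs
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    alignment = aligner.align(seq_a, seq_b)[0]
    return alignment


def map_protein_to_chains(
    sequence: str,
    model: StructureModel,
    min_identity: float = 0.9,
) -> tuple[ChainMapEntry, ...]:
    """Globally align a protein sequence to every chain.

    Identity is matched positions over the shorter of the two sequences, so
    a chain missing disordered termini still maps cleanly.  Chains below
    ``min_identity`` are omitted; an empty result means unmapped.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    entries = []
    for chain_id in sorted(model.chains):
        chain_seq = model.chain_sequence(chain_id)
        if not chain_seq:
            continue
        alignment = _align_identity(sequence, chain_seq)
        matches = 0
        residue_map: dict[int, str] = {}
        for (a0, a1), (b0, b1) in zip(*alignment.aligned):
            for off in range(int(a1) - int(a0)):
                i, j = int(a0) + off, int(b0) + off
                if sequence[i] == chain_seq[j]:
                    matches += 1
                residue_map[i + 1] = model.chains[chain_id][j][0]
        identity = matches / min(len(sequence), len(chain_seq))
        if identity >= min_identity:
            entries.append(
                ChainMapEntry(chain_id=chain_id, identity=identity,
                              residue_map=residue_map)
            )
    return tuple(entries)


def build_chain_map(
    sequences: Mapping[str, str],
    model: StructureModel,
    min_identity: float = 0.9,
) -> ChainMap:
    """Map every protein accession in ``sequences`` onto the model."""
    return {
        acc: map_protein_to_chains(seq, model, min_identity)
        for acc, seq in sequences.items()
    }


@dataclass(frozen=True)
class DistanceRecord:
    """Minimum Calpha-Calpha distance for one cross-linked pair."""

    pair: LinkPair
    mapped: bool
    min_distance: float = math.nan
    chain_pair: Optional[tuple[str, str]] = None
    compatible_strict: bool = False
    compatible_relaxed: bool = False


def pair_distance(
    pair: LinkPair,
    chain_map: ChainMap,
    model: StructureModel,
    cutoff_strict: float = 22.0,
    cutoff_relaxed: float = 30.0,
    cross_copy_for_intra: bool = False,
    restrict_chains: Optional[Iterable[str]] = None,
) -> DistanceRecord:
    """Minimum Calpha distance over all consistent chain assignments.

    For intra-protein pairs only same-chain assignments are considered
    unless ``cross_copy_for_intra`` (useful when apparent long distances
    may reflect contacts between complex copies).  ``restrict_chains``
    limits the search to a single assembly instance.  Cutoffs are
    inclusive.
    """
    (acc1, res1), (acc2, res2) = pair.site_1, pair.site_2
    entries1 = chain_map.get(acc1, ())
    entries2 = chain_map.get(acc2, ())
    if restrict_chains is not None:
        allowed = set(restrict_chains)
        entries1 = tuple(e for e in entries1 if e.chain_id in allowed)
        entries2 = tuple(e for e in entries2 if e.chain_id in allowed)
    intra = acc1 == acc2
    best: Optional[float] = None
    best_chains: Optional[tuple[str, str]] = None
    for e1 in entries1:
        key1 = e1.residue_map.get(res1)
        if key1 is None:
            continue
        ca1 = model.ca(e1.chain_id, key1)
        if ca1 is None:
            continue
        for e2 in entries2:
            if intra and not cross_copy_for_intra and e2.chain_id != e1.chain_id:
                continue
            key2 = e2.residue_map.get(res2)
            if key2 is None:
                continue
            ca2 = model.ca(e2.chain_id, key2)
            if ca2 is None:
                continue
            d = float(np.linalg.norm(ca1 - ca2))
            if best is None or d < best:
                best = d
                best_chains = (e1.chain_id, e2.chain_id)
    if best is None:
        return DistanceRecord(pair=pair, mapped=False)
    return DistanceRecord(
        pair=pair,
        mapped=True,
        min_distance=best,
        chain_pair=best_chains,
        compatible_strict=best <= cutoff_strict,
        compatible_relaxed=best <= cutoff_relaxed,
    )


@dataclass(frozen=True)
class CompatibilitySummary:
    """Compatible fractions at each cutoff, overall and per stratum."""

    n_total: int
    n_mapped: int
    fractions: Mapping[float, float]             # cutoff -> overall fraction
    strata: Mapping[str, Mapping[float, float]] = field(default_factory=dict)
    strata_n: Mapping[str, int] = field(default_factory=dict)


def compatibility_summary(
    records: Sequence[DistanceRecord],
    cutoffs: Sequence[float] = (22.0, 30.0),
) -> CompatibilitySummary:
    """Fractions of mapped pairs within each distance cutoff.

    Unmapped records are excluded from every denominator (and the
    denominators are always reported).  Stratified by the pair
    classification when present.
    """
    mapped = [r for r in records if r.mapped]
    if not mapped:
        raise ValueError("no mapped records to summarize")

    def frac(rs: Sequence[DistanceRecord], cutoff: float) -> float:
        return sum(r.min_distance <= cutoff for r in rs) / len(rs)

    strata: dict[str, dict[float, float]] = {}
    strata_n: dict[str, int] = {}
    for cls in sorted({r.pair.classification for r in mapped}):
        rs = [r for r in mapped if r.pair.classification == cls]
        strata[cls] = {c: frac(rs, c) for c in cutoffs}
        strata_n[cls] = len(rs)
    return CompatibilitySummary(
        n_total=len(records),
        n_mapped=len(mapped),
        fractions={c: frac(mapped, c) for c in cutoffs},
        strata=strata,
        strata_n=strata_n,
    )
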