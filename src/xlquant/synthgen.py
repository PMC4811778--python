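"""Synthetic data generation with ground truth.

Every stage of the pipeline is testable without downloads: MS1 runs with
isotope-paired precursor envelopes at known heavy/light ratios, search
reports with a known true pair set, and Calpha-only toy structures.  All
generators are pure functions of their configuration and seed.

The MS1 simulator places averagine isotope envelopes for the light (d0)
and heavy (d6) form of each species at the theoretical m/z, with Gaussian
elution, heavy apex = light apex x true ratio, multiplicative log-normal
intensity noise, an additive baseline floor, and per-peak m/z jitter.
Interference is modeled as independent co-eluting species listed
explicitly in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import (
    Channel,
    DEFAULT_MASS_TABLE,
    LinkedSpecies,
    LinkerSpec,
    MassTable,
    mz_from_mass,
    species_mass,
)
from .msio import Ms1Run, Ms1Scan
from .quant import IsotopeEnvelope, predict_envelope

__all__ = [
    "SpeciesSim",
    "InterferenceSim",
    "SimulationConfig",
    "simulate_ms1_run",
    "simulate_link_report",
    "make_toy_structure",
]


@dataclass(frozen=True)
class SpeciesSim:
    """One simulated cross-linked species with its ground-truth ratio."""

    species: LinkedSpecies
    true_ratio: float                  # heavy/light
    apex_time: float                   # s
    apex_intensity: float = 1e6
    peak_width: float = 6.0            # Gaussian sigma, s

    def __post_init__(self) -> None:
        if self.true_ratio < 0:
            raise ValueError("true ratio must be >= 0")
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")


@dataclass(frozen=True)
class InterferenceSim:
    """A co-eluting interfering envelope at an arbitrary m/z."""

    mz: float
    apex_time: float
    apex_intensity: float
    peak_width: float = 6.0
    charge: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    species: tuple[SpeciesSim, ...]
    interferences: tuple[InterferenceSim, ...] = ()
    rt_start: float = 0.0
    rt_end: float = 300.0
    scan_interval: float = 1.0          # s
    noise_cv: float = 0.0               # multiplicative log-normal CV
    baseline: float = 0.0               # additive floor intensity
    mz_jitter_ppm: float = 0.0
    envelope_truncation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_end <= self.rt_start or self.scan_interval <= 0:
            raise ValueError("invalid retention-time grid")
        if self.noise_cv < 0 or self.baseline < 0:
            raise ValueError("noise parameters must be >= 0")


def simulate_ms1_run(
    cfg: SimulationConfig,
    linker: LinkerSpec,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> tuple[Ms1Run, pd.DataFrame]:
    """Simulate a centroided MS1 run plus its ground-truth table.

    The truth table lists, per species: light monoisotopic m/z, true
    heavy/light ratio, apex time, charge, and neutral mass.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(cfg.rt_start, cfg.rt_end + 1e-9, cfg.scan_interval)
    # peak placement: (mz, apex_intensity, apex_time, width) per envelope peak
    placements: list[tuple[float, float, float, float]] = []
    truth_rows = []
    for idx, sim in enumerate(cfg.species):
        d0 = replace(sim.species, channel=Channel.D0)
        mass_d0 = species_mass(d0, linker, table)
        z = sim.species.charge
        envelope = predict_envelope(mass_d0, cfg.envelope_truncation)
        mz_mono = mz_from_mass(mass_d0, z, table)
        for offset, abundance in zip(envelope.offsets, envelope.abundances):
            mz_l = mz_from_mass(mass_d0 + offset, z, table)
            mz_h = mz_from_mass(mass_d0 + linker.label_delta + offset, z, table)
            light_apex = sim.apex_intensity * abundance
            placements.append((mz_l, light_apex, sim.apex_time, sim.peak_width))
            placements.append(
                (mz_h, light_apex * sim.true_ratio, sim.apex_time, sim.peak_width)
            )
        truth_rows.append(
            {
                "species_index": idx,
                "peptide_a": sim.species.peptide_a,
                "peptide_b": sim.species.peptide_b,
                "link_type": sim.species.link_type.value,
                "charge": z,
                "neutral_mass_d0": mass_d0,
                "mz_mono_d0": mz_mono,
                "true_ratio": sim.true_ratio,
                "apex_time": sim.apex_time,
                "apex_intensity": sim.apex_intensity,
            }
        )
    for interf in cfg.interferences:
        placements.append(
            (interf.mz, interf.apex_intensity, interf.apex_time, interf.peak_width)
        )

    scans = []
    for t in times:
        mzs, intens = [], []
        for mz, apex, apex_t, width in placements:
            inten = apex * np.exp(-0.5 * ((t - apex_t) / width) ** 2)
            if inten < 1e-3:
                continue
            if cfg.noise_cv > 0:
                sigma_ln = np.sqrt(np.log(1.0 + cfg.noise_cv**2))
                inten *= rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
            if cfg.mz_jitter_ppm > 0:
                mz = mz * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6))
            mzs.append(mz)
            intens.append(inten + cfg.baseline)
        scans.append(Ms1Scan(rt=float(t), mz=np.array(mzs), intensity=np.array(intens)))
    run = Ms1Run(scans=tuple(scans), run_id=f"sim-seed{cfg.seed}")
    return run, pd.DataFrame(truth_rows)


def simulate_link_report(
    n_proteins: int = 20,
    n_pairs: int = 50,
    decoy_fraction: float = 0.3,
    spectra_per_pair: tuple[int, int] = (1, 6),
    seed: int = 0,
    protein_prefix: str = "PROT",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a search report with a known true pair set.

    True pairs get E-value < 0.01 and FDR < 0.05; decoys exceed at least
    one threshold, so filtering at the standard thresholds recovers exactly
    the truth subset.  Each pair is supported by a uniform random number of
    spectra in ``spectra_per_pair`` (inclusive), with site order randomly
    swapped per spectrum to exercise canonicalization.

    Returns (report rows, truth table).  The report uses the default
    dialect column names and can be written with ``DataFrame.to_csv``.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    rng = np.random.default_rng(seed)
    proteins = [f"{protein_prefix}{i:03d}" for i in range(1, n_proteins + 1)]
    pairs = set()
    while len(pairs) < n_pairs:
        pa, pb = rng.choice(proteins, size=2, replace=True)
        sa, sb = int(rng.integers(1, 200)), int(rng.integers(1, 200))
        key = tuple(sorted([(str(pa), sa), (str(pb), sb)]))
        if key[0] != key[1]:
            pairs.add(key)
    pairs = sorted(pairs)
    n_decoys = int(round(decoy_fraction * n_pairs))
    is_decoy = np.zeros(len(pairs), dtype=bool)
    is_decoy[rng.choice(len(pairs), size=n_decoys, replace=False)] = True

    rows, truth = [], []
    spec_no = 0
    for i, ((pa, sa), (pb, sb)) in enumerate(pairs):
        n_spec = int(rng.integers(spectra_per_pair[0], spectra_per_pair[1] + 1))
        if is_decoy[i]:
            # fail E-value, FDR, or both
            mode = rng.integers(0, 3)
            e_val = rng.uniform(0.02, 0.5) if mode != 1 else rng.uniform(1e-6, 0.009)
            fdr = rng.uniform(0.06, 0.5) if mode != 0 else rng.uniform(0.0, 0.049)
        else:
            e_val = rng.uniform(1e-8, 0.009)
            fdr = rng.uniform(0.0, 0.049)
        for _ in range(n_spec):
            swap = bool(rng.integers(0, 2))
            a, b = ((pb, sb), (pa, sa)) if swap else ((pa, sa), (pb, sb))
            spec_no += 1
            rows.append(
                {
                    "spectrum": f"scan{spec_no:05d}",
                    "raw_file": "sim.raw",
                    "link_type": "inter",
                    "protein_a": a[0],
                    "site_a": a[1],
                    "protein_b": b[0],
                    "site_b": b[1],
                    "peptide_a": "PEPTIDEK",
                    "peptide_b": "LINKEDKR",
                    "charge": int(rng.integers(3, 6)),
                    "e_value": e_val * rng.uniform(0.5, 1.0),
                    "fdr": fdr,
                    "channel": "d0",
                }
            )
        truth.append(
            {
                "protein_1": pa,
                "site_1": sa,
                "protein_2": pb,
                "site_2": sb,
                "decoy": bool(is_decoy[i]),
                "n_spectra": n_spec,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_toy_structure(
    chain_specs: Sequence[tuple],
    start_resnum: int = 1,
) -> str:
    """Minimal Calpha-only PDB text for the given chains.

    ``chain_specs`` entries are ``(chain id, [CA coordinates])`` — all
    residues lysine — or ``(chain id, [CA coordinates], sequence)`` with a
    one-letter sequence of the same length.  Residues are numbered
    consecutively from ``start_resnum`` per chain.  The emitted text
    round-trips exactly through ``structmap.load_structure``.
    """
    if not chain_specs:
        raise ValueError("no chains specified")
    lines = []
    serial = 0
    for spec in chain_specs:
        chain_id, coords = spec[0], list(spec[1])
        sequence = spec[2] if len(spec) > 2 else "K" * len(coords)
        if not coords:
            raise ValueError(f"chain {chain_id!r} has no residues")
        if len(sequence) != len(coords):
            raise ValueError(f"chain {chain_id!r}: sequence/coordinate mismatch")
        res_name = "LYS"
        for i, (x, y, z) in enumerate(coords):
            if not all(np.isfinite([x, y, z])):
                raise ValueError("coordinates must be finite")
            serial += 1
            res_name = _THREE_LETTER[sequence[i]]
            lines.append(
                f"ATOM  {serial:5d}  CA  {res_name} {chain_id}{start_resnum + i:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append(f"TER   {serial + 1:5d}      {res_name} "
                     f"{chain_id}{start_resnum + len(coords) - 1:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
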