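"""Isotope-pair quantification of cross-linked peptides from MS1 data.

The light (d0) and heavy (d6) forms of an isotope-coded cross-link co-elute
and differ by a fixed label delta.  For each identified spectrum an
extracted ion chromatogram (EIC) is built per isotopic peak of both
precursor forms, and the heavy/light ratio is estimated by least-squares
regression through the origin:

    Y = a X + e,   a_hat = sum(X_j Y_j) / sum(X_j^2)

with the standard error of a_hat

    sigma_hat = sqrt( sum((Y_j - a_hat X_j)^2) / ((K - 1) sum(X_j^2)) )

normalized to a confidence score sigma = min(1, sigma_hat / a_hat) in
[0, 1]: 0 means an interference-free fit, 1 means the paired signal is
inundated by interference.  Per-spectrum ratios with sigma >= 0.5 are
discarded; the median of the survivors is the cross-link's ratio, which can
then be normalized to the median ratio of a spike-in protein (BSA) added
equally to both channels.  Cross-links present in only one state have no
finite ratio and are handled by all-or-none detection on the EIC areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .chem import Channel, LinkedSpecies, LinkerSpec, MassTable, DEFAULT_MASS_TABLE, \
    mz_from_mass, species_mass
from .msio import Ms1Run

__all__ = [
    "IsotopeEnvelope",
    "EicPair",
    "RatioEstimate",
    "PeakStrategy",
    "SiteQuant",
    "AllOrNone",
    "ReciprocalCall",
    "predict_envelope",
    "extract_eic_pair",
    "fit_ratio",
    "confidence_score",
    "quantify_eic_pair",
    "choose_peak_ratio",
    "aggregate_link",
    "normalize_to_spikein",
    "detect_all_or_none",
    "reciprocal_combine",
]

# Spacing between adjacent isotopic peaks (13C-12C mass difference, Da).
ISOTOPE_SPACING = 1.0033548

# Averagine model residue: average elemental composition per 111.1254 Da of
# peptide mass, used to predict isotope envelopes when the exact
# composition is unknown.
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

# Isotope abundance patterns per element, indexed by extra neutron count.
_ISOTOPE_PATTERNS = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Predicted isotopic peak offsets (Da) and base-peak-relative abundances."""

    offsets: tuple[float, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.offsets or self.offsets[0] != 0.0:
            raise ValueError("envelope must start at the monoisotopic peak")

    @property
    def most_abundant_index(self) -> int:
        return int(np.argmax(self.abundances))


def _element_distribution(pattern: Sequence[float], n: int) -> np.ndarray:
    """Neutron-count distribution of n atoms of one element (convolution power)."""
    base = np.asarray(pattern, dtype=float)
    result = np.array([1.0])
    power = base
    k = n
    while k:
        if k & 1:
            result = np.convolve(result, power)[:12]
        k >>= 1
        if k:
            power = np.convolve(power, power)[:12]
    return result


def predict_envelope(neutral_mass: float, truncation: float = 0.05,
                     max_peaks: int = 8) -> IsotopeEnvelope:
    """Averagine isotope envelope for a species of the given neutral mass.

    Peaks below ``truncation`` of the base peak are dropped and at most
    ``max_peaks`` are kept, renormalized so the base peak is 1.0.
    """
    if neutral_mass <= 0:
        raise ValueError("mass must be positive")
    units = neutral_mass / _AVERAGINE_MASS
    dist = np.array([1.0])
    for element, coeff in _AVERAGINE.items():
        n = int(round(coeff * units))
        if n > 0:
            dist = np.convolve(dist, _element_distribution(_ISOTOPE_PATTERNS[element], n))[:12]
    dist = dist / dist.max()
    keep = min(max_peaks, len(dist))
    offsets, abundances = [], []
    for i in range(keep):
        if dist[i] >= truncation or i == 0:
            offsets.append(i * ISOTOPE_SPACING)
            abundances.append(float(dist[i]))
        elif i > int(np.argmax(dist)):
            break
    return IsotopeEnvelope(offsets=tuple(offsets), abundances=tuple(abundances))


@dataclass(frozen=True)
class EicPair:
    """Per-isotopic-peak light/heavy chromatogram traces on a shared RT grid."""

    rt_grid: np.ndarray                     # seconds
    light: np.ndarray                       # (n_isotope_peaks, n_scans)
    heavy: np.ndarray
    window: tuple[int, int]                 # integration bounds, grid indices [lo, hi)
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        if self.light.shape != self.heavy.shape:
            raise ValueError("light and heavy traces must share shape")
        if self.light.shape[1] != len(self.rt_grid):
            raise ValueError("traces must be sampled on the RT grid")

    @property
    def n_peaks(self) -> int:
        return self.light.shape[0]

    def windowed(self, peak: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.window
        return self.light[peak, lo:hi], self.heavy[peak, lo:hi]


def _sum_within_ppm(scan_mz: np.ndarray, scan_int: np.ndarray,
                    target: float, tol_ppm: float) -> float:
    tol = target * tol_ppm * 1e-6
    lo = np.searchsorted(scan_mz, target - tol, side="left")
    hi = np.searchsorted(scan_mz, target + tol, side="right")
    return float(scan_int[lo:hi].sum())


def _integration_window(signal: np.ndarray, center_idx: int,
                        rel_floor: float = 0.01) -> tuple[int, int]:
    """Contiguous above-baseline region around the apex nearest the center."""
    if signal.max() <= 0:
        return 0, len(signal)
    floor = rel_floor * signal.max()
    above = signal > floor
    if not above[center_idx]:
        candidates = np.flatnonzero(above)
        center_idx = int(candidates[np.argmin(np.abs(candidates - center_idx))])
    lo = center_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = center_idx + 1
    while hi < len(signal) and above[hi]:
        hi += 1
    return lo, hi


def extract_eic_pair(
    run: Ms1Run,
    species: LinkedSpecies,
    linker: LinkerSpec,
    envelope: IsotopeEnvelope,
    rt_center: float,
    tol_ppm: float = 10.0,
    rt_window: float = 90.0,
    table: MassTable = DEFAULT_MASS_TABLE,
    spectrum_id: str = "",
) -> EicPair:
    """Build paired light/heavy EICs for one identified species.

    For isotope peak j the light trace follows m/z(d0) + offset_j / z and
    the heavy trace m/z(d0 + label delta) + offset_j / z, summing intensity
    within ``tol_ppm`` per scan over scans within ``rt_window`` seconds of
    ``rt_center``.  A species absent from the run yields all-zero traces.
    """
    start, end = run.rt_span
    if not (start - rt_window <= rt_center <= end + rt_window):
        raise ValueError(
            f"rt_center {rt_center:.1f}s outside run span [{start:.1f}, {end:.1f}]s"
        )
    d0 = replace(species, channel=Channel.D0)
    mass_d0 = species_mass(d0, linker, table)
    z = species.charge
    scans = [s for s in run.scans if abs(s.rt - rt_center) <= rt_window]
    if not scans:
        raise ValueError("retention-time window contains no scans")
    grid = np.array([s.rt for s in scans])
    n_peaks = len(envelope.offsets)
    light = np.zeros((n_peaks, len(scans)))
    heavy = np.zeros((n_peaks, len(scans)))
    for j, offset in enumerate(envelope.offsets):
        mz_l = mz_from_mass(mass_d0 + offset, z, table)
        mz_h = mz_from_mass(mass_d0 + linker.label_delta + offset, z, table)
        for i, scan in enumerate(scans):
            light[j, i] = _sum_within_ppm(scan.mz, scan.intensity, mz_l, tol_ppm)
            heavy[j, i] = _sum_within_ppm(scan.mz, scan.intensity, mz_h, tol_ppm)
    combined = light.sum(axis=0) + heavy.sum(axis=0)
    center_idx = int(np.argmin(np.abs(grid - rt_center)))
    window = _integration_window(combined, center_idx)
    return EicPair(rt_grid=grid, light=light, heavy=heavy, window=window,
                   spectrum_id=spectrum_id)


def fit_ratio(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares regression through the origin with standard error.

    Returns ``(a_hat, sigma_hat)`` where a_hat = sum(xy)/sum(x^2) and
    sigma_hat = sqrt(sum((y - a_hat x)^2) / ((K-1) sum(x^2))).  Raises on a
    degenerate light channel (all-zero x) — callers should route those
    through all-or-none detection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    k = len(x)
    if k < 2:
        raise ValueError("need at least two grid points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ZeroDivisionError("sum(x^2) is zero; light channel empty")
    a_hat = float(x @ y) / sxx
    residuals = y - a_hat * x
    sigma_hat = math.sqrt(float(residuals @ residuals) / ((k - 1) * sxx))
    return a_hat, sigma_hat


def confidence_score(a_hat: float, sigma_hat: float) -> float:
    """Normalize the ratio's standard error to [0, 1].

    0 is an interference-free (perfect) fit; 1 means the signal is swamped.
    Defined as min(1, sigma_hat / a_hat); a non-positive ratio scores 1.
    """
    if not (math.isfinite(a_hat) and math.isfinite(sigma_hat)):
        return 1.0
    if a_hat <= 0:
        return 1.0
    return min(1.0, sigma_hat / a_hat)


class PeakStrategy(str, Enum):
    MONOISOTOPIC = "monoisotopic"
    MOST_INTENSE = "most_intense"
    LEAST_INTERFERED = "least_interfered"


@dataclass(frozen=True)
class RatioEstimate:
    """Per-spectrum heavy/light ratio with its confidence score."""

    a_hat: float
    sigma_hat: float
    sigma: float
    strategy: PeakStrategy
    peak_index: int
    k: int
    spectrum_id: str = ""
    degenerate: Optional[str] = None     # only_light / only_heavy / empty

    def __post_init__(self) -> None:
        if self.degenerate is None and not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")


def quantify_eic_pair(
    pair: EicPair, strategy: PeakStrategy = PeakStrategy.LEAST_INTERFERED
) -> RatioEstimate:
    """Fit per-isotope-peak ratios on the integration window and pick one."""
    estimates = []
    areas = []
    for j in range(pair.n_peaks):
        x, y = pair.windowed(j)
        areas.append(float(x.sum() + y.sum()))
        if float(x @ x) == 0.0 or len(x) < 2:
            estimates.append(None)
            continue
        a_hat, sigma_hat = fit_ratio(x, y)
        estimates.append(
            RatioEstimate(
                a_hat=a_hat,
                sigma_hat=sigma_hat,
                sigma=confidence_score(a_hat, sigma_hat),
                strategy=strategy,
                peak_index=j,
                k=len(x),
                spectrum_id=pair.spectrum_id,
            )
        )
    if all(e is None for e in estimates):
        flag = detect_all_or_none(pair)
        return RatioEstimate(
            a_hat=math.nan, sigma_hat=math.nan, sigma=1.0, strategy=strategy,
            peak_index=0, k=0, spectrum_id=pair.spectrum_id,
            degenerate=flag.value,
        )
    return choose_peak_ratio(estimates, strategy, areas)


def choose_peak_ratio(
    estimates: Sequence[Optional[RatioEstimate]],
    strategy: PeakStrategy,
    areas: Optional[Sequence[float]] = None,
) -> RatioEstimate:
    """Select the reported per-spectrum estimate from per-peak estimates.

    monoisotopic: peak 0; most_intense: the peak with the largest summed
    light+heavy area; least_interfered: the peak with minimal sigma.
    """
    valid = [(j, e) for j, e in enumerate(estimates) if e is not None]
    if not valid:
        raise ValueError("no valid per-peak estimates")
    strategy = PeakStrategy(strategy)
    if strategy is PeakStrategy.MONOISOTOPIC:
        if estimates[0] is None:
            raise ValueError("monoisotopic peak has no valid estimate")
        chosen = estimates[0]
    elif strategy is PeakStrategy.MOST_INTENSE:
        if areas is None:
            raise ValueError("most_intense strategy needs per-peak areas")
        chosen = max(valid, key=lambda je: areas[je[0]])[1]
    else:
        chosen = min(valid, key=lambda je: je[1].sigma)[1]
    return replace(chosen, strategy=strategy)


class AllOrNone(str, Enum):
    NONE = "none"
    ONLY_LIGHT = "only_light"
    ONLY_HEAVY = "only_heavy"


def detect_all_or_none(pair: EicPair, floor_multiplier: float = 3.0) -> AllOrNone:
    """Flag species present in only one channel.

    The noise floor is ``floor_multiplier`` times the median nonzero
    intensity across both full traces; a channel whose integrated window
    area stays below one floor-level scan equivalent counts as absent.
    Both channels empty is unquantifiable, not all-or-none.
    """
    lo, hi = pair.window
    light_area = float(pair.light[:, lo:hi].sum())
    heavy_area = float(pair.heavy[:, lo:hi].sum())
    nonzero = np.concatenate([pair.light.ravel(), pair.heavy.ravel()])
    nonzero = nonzero[nonzero > 0]
    if nonzero.size == 0:
        return AllOrNone.NONE
    floor = floor_multiplier * float(np.median(nonzero))
    if heavy_area < floor <= light_area:
        return AllOrNone.ONLY_LIGHT
    if light_area < floor <= heavy_area:
        return AllOrNone.ONLY_HEAVY
    return AllOrNone.NONE


@dataclass(frozen=True)
class SiteQuant:
    """Aggregated quantification for one cross-link or mono-link site."""

    link_id: str
    median_ratio: Optional[float]
    n_spectra_used: int
    normalized_ratio: Optional[float] = None
    all_or_none: AllOrNone = AllOrNone.NONE


def aggregate_link(
    link_id: str,
    estimates: Iterable[RatioEstimate],
    sigma_cutoff: float = 0.5,
    eic_pairs: Sequence[EicPair] = (),
) -> SiteQuant:
    """Median of per-spectrum ratios passing the sigma cutoff.

    Estimates with sigma >= ``sigma_cutoff`` are discarded.  If none
    survive, all-or-none detection is attempted on the supplied EICs
    (majority flag wins).
    """
    kept = [
        e.a_hat
        for e in estimates
        if e.degenerate is None and e.sigma < sigma_cutoff and math.isfinite(e.a_hat)
    ]
    if kept:
        return SiteQuant(link_id=link_id, median_ratio=median(kept),
                         n_spectra_used=len(kept))
    flags = [detect_all_or_none(p) for p in eic_pairs]
    flags = [f for f in flags if f is not AllOrNone.NONE]
    flag = AllOrNone.NONE
    if flags:
        flag = max(set(flags), key=flags.count)
    return SiteQuant(link_id=link_id, median_ratio=None, n_spectra_used=0,
                     all_or_none=flag)


def normalize_to_spikein(
    quants: Sequence[SiteQuant], spikein_prefix: str
) -> list[SiteQuant]:
    """Divide every ratio by the median ratio of the spike-in protein.

    Spike-in quants are those whose link_id starts with ``spikein_prefix``
    (e.g. the BSA accession).  Raises if no spike-in ratio is available so
    the caller must skip normalization explicitly.
    """
    spike = [
        q.median_ratio
        for q in quants
        if q.link_id.startswith(spikein_prefix) and q.median_ratio is not None
    ]
    if not spike:
        raise ValueError(
            f"no quantified spike-in links matching {spikein_prefix!r}; "
            "skip normalization explicitly if none was spiked in"
        )
    factor = median(spike)
    return [
        replace(q, normalized_ratio=(q.median_ratio / factor
                                     if q.median_ratio is not None else None))
        for q in quants
    ]


@dataclass(frozen=True)
class ReciprocalCall:
    """Forward/reverse labeling consistency for one link."""

    link_id: str
    forward_ratio: Optional[float]      # state1/state2, forward experiment
    reverse_ratio: Optional[float]      # state1/state2, reverse experiment
    consistent_change: bool
    direction: str = "unchanged"        # up / down / unchanged / unpaired


def _oriented(ratio: Optional[float], state1_channel: str) -> Optional[float]:
    # Measured ratios are heavy/light (d6/d0). If state1 carried the d6
    # label the measured ratio already is state1/state2; otherwise invert.
    if ratio is None:
        return None
    if state1_channel == "d6":
        return ratio
    if ratio == 0:
        return math.inf
    return 1.0 / ratio


def reciprocal_combine(
    forward: Mapping[str, Optional[float]],
    reverse: Mapping[str, Optional[float]],
    fold_threshold: float = 5.0,
    forward_state1_channel: str = "d0",
    reverse_state1_channel: str = "d6",
) -> list[ReciprocalCall]:
    """Combine forward- and reverse-labeled experiments into consistency calls.

    Inputs map link ids to measured heavy/light median ratios; the channel
    assignments say which isotope the first biological state carried in
    each experiment.  Both ratios are re-oriented to state1/state2; a link
    changes consistently iff both oriented ratios exceed the fold threshold
    on the same side.  Links quantified in only one experiment are reported
    unpaired and never consistent.
    """
    if fold_threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    calls = []
    for link_id in sorted(set(forward) | set(reverse)):
        f = _oriented(forward.get(link_id), forward_state1_channel)
        r = _oriented(reverse.get(link_id), reverse_state1_channel)
        if f is None or r is None:
            calls.append(ReciprocalCall(link_id, f, r, False, "unpaired"))
            continue
        up = f > fold_threshold and r > fold_threshold
        down = f < 1.0 / fold_threshold and r < 1.0 / fold_threshold
        direction = "up" if up else "down" if down else "unchanged"
        calls.append(ReciprocalCall(link_id, f, r, up or down, direction))
    return calls
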