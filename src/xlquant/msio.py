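"""MS data containers and readers.

``Ms1Run`` holds a sequence of centroided MS1 scans (retention time plus
sorted m/z / intensity arrays).  Runs can be read from mzML (via pyteomics)
or from a minimal plain-text format used for fixtures:

    # run: <run id>
    SCAN <retention time, s>
    <m/z> <intensity>
    ...

MS2 peak lists are read from MGF (via pyteomics) or a two-column text
dialect (one ``m/z intensity`` pair per line).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .chem import Ms2Spectrum

__all__ = [
    "Ms1Scan",
    "Ms1Run",
    "read_text_run",
    "write_text_run",
    "read_mzml_run",
    "read_mgf",
    "read_peaklist",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class Ms1Scan:
    rt: float                 # retention time, seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])


@dataclass(frozen=True)
class Ms1Run:
    scans: tuple[Ms1Scan, ...]
    run_id: str = "run"
    polarity: str = "positive"

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rt_span(self) -> tuple[float, float]:
        if not self.scans:
            raise ValueError("empty run")
        return self.scans[0].rt, self.scans[-1].rt


def write_text_run(run: Ms1Run, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# run: {run.run_id}\n")
        for scan in run.scans:
            fh.write(f"SCAN {scan.rt:.6f}\n")
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")


def read_text_run(path: PathLike) -> Ms1Run:
    run_id = Path(path).stem
    scans: list[Ms1Scan] = []
    rt: float | None = None
    mzs: list[float] = []
    intens: list[float] = []

    def flush() -> None:
        nonlocal mzs, intens
        if rt is not None:
            scans.append(Ms1Scan(rt=rt, mz=np.array(mzs), intensity=np.array(intens)))
        mzs, intens = [], []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# run:"):
                    run_id = line.split(":", 1)[1].strip()
                continue
            if line.startswith("SCAN"):
                flush()
                rt = float(line.split()[1])
            else:
                a, b = line.split()
                mzs.append(float(a))
                intens.append(float(b))
    flush()
    return Ms1Run(scans=tuple(scans), run_id=run_id)


def read_mzml_run(path: PathLike) -> Ms1Run:
    """Read centroided MS1 scans from an mzML file."""
    from pyteomics import mzml

    scans: list[Ms1Scan] = []
    with mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = float(
                spec["scanList"]["scan"][0]["scan start time"]
            )
            unit = spec["scanList"]["scan"][0].get(
                "scan start time unit_accession", ""
            )
            # mzML scan times are usually minutes; normalize to seconds.
            if "UO:0000031" in str(unit) or rt < 1e3:
                rt *= 60.0
            scans.append(
                Ms1Scan(
                    rt=rt,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                )
            )
    scans.sort(key=lambda s: s.rt)
    return Ms1Run(scans=tuple(scans), run_id=Path(path).stem)


def read_mgf(path: PathLike) -> list[Ms2Spectrum]:
    from pyteomics import mgf

    out: list[Ms2Spectrum] = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            pep = params.get("pepmass")
            out.append(
                Ms2Spectrum(
                    scan_id=str(params.get("title", len(out))),
                    peaks=tuple(
                        zip(map(float, spec["m/z array"]),
                            map(float, spec["intensity array"]))
                    ),
                    precursor_mz=float(pep[0]) if pep else None,
                    precursor_charge=charge,
                )
            )
    return out


def read_peaklist(source: Union[PathLike, io.TextIOBase],
                  scan_id: str = "peaklist") -> Ms2Spectrum:
    """Read the minimal two-column ``m/z intensity`` MS2 dialect."""
    if isinstance(source, (str, Path)):
        fh: Iterable[str] = open(source)
        scan_id = Path(source).stem
    else:
        fh = source
    peaks = []
    for line in fh:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()[:2]
        peaks.append((float(a), float(b)))
    return Ms2Spectrum(scan_id=scan_id, peaks=tuple(peaks))
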