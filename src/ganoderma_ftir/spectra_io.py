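"""Reading, writing and partitioning of spectra.

CSV layout is the wide interchange format: header row carries the wavenumbers,
first column the sample id, second column the class label, remaining columns
the absorbance values.  JCAMP-DX (4.24, AFFN ``(X++(Y..Y))`` tables) is
supported read-only as the common FTIR exchange format.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectraSet

__all__ = [
    "DatasetSplit",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
    "stratified_split",
]


@dataclass(frozen=True)
class DatasetSplit:
    """Calibration/validation partition of a sample-id set."""

    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        cal, val = set(self.calibration_ids), set(self.validation_ids)
        if cal & val:
            raise ValueError("calibration and validation ids overlap")


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    df = pd.DataFrame(spectra.absorbance, columns=[repr(float(w)) for w in spectra.wavenumbers])
    df.insert(0, "label", spectra.labels)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path) -> SpectraSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "sample_id" or df.columns[1] != "label":
        raise ValueError("expected 'sample_id' and 'label' as first two columns")
    try:
        wn = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber header: {exc}") from None
    diffs = np.diff(wn)
    if wn.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("wavenumber header must be strictly monotone")
    absorbance = df.iloc[:, 2:].to_numpy(dtype=float)
    ids = [str(s) for s in df["sample_id"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    return SpectraSet(
        wavenumbers=wn,
        absorbance=absorbance,
        labels=df["label"].to_numpy(dtype=object),
        sample_ids=ids,
    )


_JCAMP_LABEL = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")
_AFFN_TOKEN = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcamp(path: str | Path, sample_id: str | None = None) -> SpectraSet:
    """Parse a single-spectrum JCAMP-DX file with an AFFN (X++(Y..Y)) table.

    Transmittance spectra are converted to absorbance via -log10(T); percent
    transmittance is divided by 100 first.  Compressed (SQZ/DIF/DUP) tables
    are rejected.
    """
    text = Path(path).read_text()
    records: dict[str, str] = {}
    data_lines: list[str] = []
    in_table = False
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        m = _JCAMP_LABEL.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            if in_table:
                in_table = False
            if key == "XYDATA":
                if "(X++(Y..Y))" not in m.group(2).replace(" ", ""):
                    raise ValueError("only (X++(Y..Y)) XYDATA tables are supported")
                in_table = True
            records[key] = m.group(2).strip()
        elif in_table:
            data_lines.append(line)

    for required in ("XYDATA", "NPOINTS", "FIRSTX", "LASTX"):
        if required not in records:
            raise ValueError(f"missing required JCAMP label ##{required}")

    npoints = int(float(records["NPOINTS"]))
    firstx = float(records["FIRSTX"])
    lastx = float(records["LASTX"])
    xfactor = float(records.get("XFACTOR", "1"))
    yfactor = float(records.get("YFACTOR", "1"))

    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        stripped = line.replace(",", " ")
        leftover = _AFFN_TOKEN.sub(" ", stripped).strip()
        if leftover:
            raise ValueError(f"unsupported (compressed?) XYDATA content: {leftover!r}")
        tokens = _AFFN_TOKEN.findall(stripped)
        if len(tokens) < 2:
            raise ValueError("XYDATA line with fewer than two values")
        xs.append(float(tokens[0]) * xfactor)
        ys.extend(float(t) * yfactor for t in tokens[1:])

    if len(ys) != npoints:
        raise ValueError(f"XYDATA truncated: expected {npoints} points, got {len(ys)}")

    if npoints > 1:
        step = (lastx - firstx) / (npoints - 1)
    else:
        step = float(records.get("DELTAX", "0"))
    if "DELTAX" in records and npoints > 1:
        deltax = float(records["DELTAX"])
        if not math.isclose(deltax, step, rel_tol=1e-3, abs_tol=1e-6):
            raise ValueError("DELTAX inconsistent with FIRSTX/LASTX/NPOINTS")
    wn = firstx + step * np.arange(npoints)
    # sanity: line-start X values must land on the reconstructed grid
    for i, x in enumerate(xs):
        idx = int(round((x - firstx) / step)) if step != 0 else 0
        if not math.isclose(wn[min(max(idx, 0), npoints - 1)], x, rel_tol=1e-3, abs_tol=1e-2):
            raise ValueError("XYDATA X values do not match the declared grid")

    y = np.asarray(ys, dtype=float)
    yunits = records.get("YUNITS", "ABSORBANCE").upper()
    if "TRANSMITTANCE" in yunits:
        t = y / 100.0 if y.max() > 1.5 else y
        if np.any(t <= 0):
            raise ValueError("non-positive transmittance cannot be converted")
        y = -np.log10(t)

    if sample_id is None:
        sample_id = records.get("TITLE", "jcamp") or "jcamp"
    return SpectraSet(
        wavenumbers=wn,
        absorbance=y[None, :],
        labels=np.asarray([records.get("$LABEL", "unknown")], dtype=object),
        sample_ids=[sample_id],
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(spectra: SpectraSet, fraction: float = 0.6, seed: int = 0) -> DatasetSplit:
    """Per-class random calibration/validation split.

    The calibration share of each class is ``round(fraction * n)`` with ties
    rounded up, so 78/20/20 at 0.6 gives 47/12/12.  Sampling is without
    replacement and reproducible from ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cal: list[str] = []
    val: list[str] = []
    for cls in spectra.classes:
        idx = np.flatnonzero(spectra.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_cal = _round_half_up(fraction * idx.size)
        n_cal = min(max(n_cal, 1), idx.size - 1)
        perm = rng.permutation(idx)
        cal.extend(spectra.sample_ids[i] for i in perm[:n_cal])
        val.extend(spectra.sample_ids[i] for i in perm[n_cal:])
    return DatasetSplit(calibration_ids=tuple(cal), validation_ids=tuple(val), fraction=fraction)
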