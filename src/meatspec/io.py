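"""Labeled spectral datasets: containers, wide-CSV and JCAMP-DX ingestion.

The central container is :class:`SpectraSet`, a samples x wavenumbers
absorbance matrix with per-row sample/replicate identifiers and a binary
origin label (1 = target class, 0 = other).  Wavenumbers are stored
ascending; descending input (the common FTIR file order) is flipped on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "RegionSpec",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
    "average_replicates",
    "apply_region",
]

METADATA_COLUMNS = ("sample_id", "replicate_id", "label")


class SpectraFormatError(ValueError):
    """Raised when a spectral file or dataset violates the format contract."""


@dataclass
class SpectraSet:
    """Absorbance matrix with wavenumber axis and per-row metadata.

    Parameters
    ----------
    wavenumbers : array of float, shape (p,)
        Spectral axis in cm^-1, strictly monotonic.  Stored ascending;
        descending input is accepted and flipped together with the columns.
    absorbance : array of float, shape (n, p)
        Absorbance in AU, one row per recorded spectrum.
    sample_id : sequence of str, length n
    replicate_id : sequence of int, length n
    label : sequence of int in {0, 1}, length n
        1 = target-origin class, 0 = other origin.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: np.ndarray
    replicate_id: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_id = np.asarray(self.sample_id, dtype=object).ravel()
        self.replicate_id = np.asarray(self.replicate_id, dtype=int).ravel()
        self.label = np.asarray(self.label, dtype=int).ravel()

        n, p = self.absorbance.shape
        if self.wavenumbers.size != p:
            raise SpectraFormatError(
                f"absorbance has {p} columns but axis has {self.wavenumbers.size} wavenumbers"
            )
        for name in ("sample_id", "replicate_id", "label"):
            if getattr(self, name).size != n:
                raise SpectraFormatError(f"{name} length does not match {n} rows")

        dw = np.diff(self.wavenumbers)
        if p > 1 and not (np.all(dw > 0) or np.all(dw < 0)):
            raise SpectraFormatError("wavenumber axis is not strictly monotonic")
        if p > 1 and dw[0] < 0:  # store ascending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()

        bad = ~np.isin(self.label, (0, 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SpectraFormatError(
                f"row {i} (sample_id={self.sample_id[i]!r}) has label "
                f"{self.label[i]}; labels must be 0 or 1"
            )
        if not np.all(np.isfinite(self.absorbance)):
            i, j = map(int, np.argwhere(~np.isfinite(self.absorbance))[0])
            raise SpectraFormatError(f"non-finite absorbance at row {i}, column {j}")

    # -- shape shorthands -------------------------------------------------
    @property
    def n(self) -> int:
        return self.absorbance.shape[0]

    @property
    def p(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        """Same metadata/axis, new absorbance matrix (shape must match)."""
        return replace(self, absorbance=np.asarray(matrix, dtype=float))

    def rows(self, idx) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[idx],
            sample_id=self.sample_id[idx],
            replicate_id=self.replicate_id[idx],
            label=self.label[idx],
        )

    def columns(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            wavenumbers=self.wavenumbers[mask],
            absorbance=self.absorbance[:, mask],
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            label=self.label,
        )


def _normalize_interval(lo: float, hi: float) -> tuple[float, float]:
    return (lo, hi) if lo <= hi else (hi, lo)


@dataclass
class RegionSpec:
    """Wavenumber intervals to keep and to drop (closed on both ends)."""

    include: Sequence[tuple[float, float]] = field(default_factory=list)
    exclude: Sequence[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.include = [_normalize_interval(*iv) for iv in self.include]
        self.exclude = [_normalize_interval(*iv) for iv in self.exclude]

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumbers, dtype=float)
        if self.include:
            keep = np.zeros(w.shape, dtype=bool)
            for lo, hi in self.include:
                keep |= (w >= lo) & (w <= hi)
        else:
            keep = np.ones(w.shape, dtype=bool)
        for lo, hi in self.exclude:
            keep &= ~((w >= lo) & (w <= hi))
        return keep

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        return cls(
            include=[tuple(iv) for iv in d.get("include", [])],
            exclude=[tuple(iv) for iv in d.get("exclude", [])],
        )


# Named regions used throughout the analysis.  The fingerprint window is
# 1800-600 cm^-1 by default (1800-850 is in circulation too and available via
# RegionSpec); the whole-spectrum window is 4000-650 cm^-1 with the
# atmospheric CO2 (2390-2250) and water-vapour (3400-3200) bands cut out.
CO2_BAND = (2250.0, 2390.0)
WATER_BAND = (3200.0, 3400.0)
FINGERPRINT_REGION = RegionSpec(include=[(600.0, 1800.0)], exclude=[CO2_BAND, WATER_BAND])
WHOLE_REGION = RegionSpec(include=[(650.0, 4000.0)], exclude=[CO2_BAND, WATER_BAND])
NAMED_REGIONS = {"fingerprint": FINGERPRINT_REGION, "whole": WHOLE_REGION}


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide-format spectra CSV.

    Layout: metadata columns ``sample_id, replicate_id, label`` first, then
    one column per wavenumber with the wavenumber value as header.
    """
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata column(s): {', '.join(missing)}")
    spectral_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not spectral_cols:
        raise SpectraFormatError("no wavenumber columns found")
    try:
        wavenumbers = np.array([float(c) for c in spectral_cols])
    except ValueError as e:
        raise SpectraFormatError(f"non-numeric wavenumber header: {e}") from e

    absorb = df[spectral_cols].to_numpy()
    if absorb.dtype.kind not in "fiu":
        for col in spectral_cols:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SpectraFormatError(
                    f"non-numeric absorbance at row {row}, column {col!r}: "
                    f"{df[col][row]!r}"
                )
        absorb = df[spectral_cols].apply(pd.to_numeric).to_numpy()
    if np.isnan(absorb).any():
        i, j = map(int, np.argwhere(np.isnan(absorb))[0])
        raise SpectraFormatError(
            f"missing/non-numeric absorbance at row {i}, column {spectral_cols[j]!r}"
        )

    labels = df["label"].to_numpy()
    bad = ~np.isin(labels, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SpectraFormatError(
            f"row {row} has label {labels[row]!r}; labels must be 0 or 1"
        )
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=absorb,
        sample_id=df["sample_id"].astype(str).to_numpy(dtype=object),
        replicate_id=df["replicate_id"].to_numpy(),
        label=labels,
    )


def write_spectra_csv(s: SpectraSet, path, descending: bool = False) -> None:
    """Write the wide CSV layout; round-trips with :func:`read_spectra_csv`.

    ``descending=True`` writes columns high-to-low wavenumber, the common
    instrument export order.
    """
    if s.n == 0 or s.p == 0:
        raise SpectraFormatError("refusing to write an empty dataset")
    w = s.wavenumbers
    a = s.absorbance
    if descending:
        w, a = w[::-1], a[:, ::-1]
    df = pd.DataFrame(a, columns=[repr(float(x)) for x in w])
    df.insert(0, "label", s.label)
    df.insert(0, "replicate_id", s.replicate_id)
    df.insert(0, "sample_id", s.sample_id)
    df.to_csv(path, index=False, float_format="%.17g")


_JCAMP_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def _jcamp_fields(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    current = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            current = key.strip().upper().replace(" ", "")
            fields[current] = value.strip()
        elif current is not None:
            fields[current] += "\n" + line
    return fields


def read_jcamp(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a single-spectrum JCAMP-DX file (AFFN XYDATA or XYPOINTS).

    Returns ``(wavenumbers, absorbance)`` with the axis ascending.  Compressed
    ordinate dialects (PAC/SQZ/DIF/DUP) are not supported and raise.
    """
    with open(path) as fh:
        text = fh.read()
    fields = _jcamp_fields(text)
    if "END" not in fields:
        raise SpectraFormatError("truncated JCAMP-DX file: missing ##END=")

    xfactor = float(fields.get("XFACTOR", "1") or 1)
    yfactor = float(fields.get("YFACTOR", "1") or 1)

    if "XYPOINTS" in fields or "XYDATA" in fields:
        key = "XYPOINTS" if "XYPOINTS" in fields else "XYDATA"
        body = fields[key]
        header, _, data = body.partition("\n")
        header = header.strip().upper().replace(" ", "")
        if key == "XYPOINTS" or "(XY..XY)" in header:
            nums = [float(m) for m in _JCAMP_NUM.findall(data)]
            if len(nums) % 2:
                raise SpectraFormatError("odd number of values in XY point list")
            x = np.array(nums[0::2]) * xfactor
            y = np.array(nums[1::2]) * yfactor
        elif "(X++(Y..Y))" in header:
            if re.search(r"[A-DF-Zа-я@%]", data, flags=re.IGNORECASE):
                raise SpectraFormatError(
                    "compressed JCAMP ordinate dialects (SQZ/DIF/DUP/PAC letters) "
                    "are not supported; only AFFN is read"
                )
            x_parts, y_parts = [], []
            for line in data.splitlines():
                nums = [float(m) for m in _JCAMP_NUM.findall(line)]
                if not nums:
                    continue
                x_parts.append(nums[0])
                y_parts.append(nums[1:])
            npoints = int(float(fields.get("NPOINTS", "0") or 0))
            ys = [v for part in y_parts for v in part]
            if npoints and len(ys) != npoints:
                raise SpectraFormatError(
                    f"XYDATA holds {len(ys)} ordinates but NPOINTS={npoints}"
                )
            firstx = float(fields["FIRSTX"]) if "FIRSTX" in fields else x_parts[0] * xfactor
            lastx = float(fields["LASTX"]) if "LASTX" in fields else None
            if lastx is not None and len(ys) > 1:
                x = np.linspace(firstx, lastx, len(ys))
            else:
                deltax = float(fields.get("DELTAX", "0") or 0)
                x = firstx + deltax * np.arange(len(ys))
            y = np.array(ys) * yfactor
        else:
            raise SpectraFormatError(f"unsupported JCAMP data form: {header}")
    else:
        raise SpectraFormatError("no XYDATA or XYPOINTS block found")

    if x.size == 0:
        raise SpectraFormatError("JCAMP file contains no data points")
    order = np.argsort(x)
    return x[order], y[order]


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average the replicate rows of each sample into one modelling row.

    Keeps first-appearance sample order.  Replicates of one sample must share
    a label.
    """
    ids, first = np.unique(s.sample_id.astype(str), return_index=True)
    ids = ids[np.argsort(first)]
    rows, labels = [], []
    sid = s.sample_id.astype(str)
    for sample in ids:
        idx = np.flatnonzero(sid == sample)
        lab = np.unique(s.label[idx])
        if lab.size != 1:
            raise SpectraFormatError(
                f"sample {sample!r} has replicates with conflicting labels {lab.tolist()}"
            )
        rows.append(s.absorbance[idx].mean(axis=0))
        labels.append(int(lab[0]))
    return SpectraSet(
        wavenumbers=s.wavenumbers,
        absorbance=np.vstack(rows),
        sample_id=np.array(ids, dtype=object),
        replicate_id=np.zeros(len(ids), dtype=int),
        label=np.array(labels),
    )


def apply_region(s: SpectraSet, region: RegionSpec) -> SpectraSet:
    """Keep columns inside an include interval and outside every exclude one."""
    keep = region.mask(s.wavenumbers)
    if not keep.any():
        raise SpectraFormatError("region selection leaves no wavenumber columns")
    return s.columns(keep)
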