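"""Core data model for visible-range absorbance spectra with SSC labels.

A :class:`SpectrumSet` is the object every pipeline stage transforms: a
samples x wavelengths absorbance matrix on a strictly increasing nm grid
(default 400..800 nm in 5 nm steps, 81 points), with optional per-sample
soluble solid content (SSC, °Brix) and a 3-level quality grade derived
from SSC through a :class:`GradeScheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "GradeScheme",
    "SpectrumSet",
    "SpectraFormatError",
    "OutOfSchemeError",
    "assign_grade",
    "read_spectra",
    "write_spectra",
    "stratified_indices",
    "stratified_split",
]

#: Default acquisition grid: 400-800 nm at 5 nm intervals (81 points).
DEFAULT_WAVELENGTHS = np.arange(400.0, 801.0, 5.0)


class SpectraFormatError(ValueError):
    """Raised for malformed spectra/metadata tables, naming the offender."""


class OutOfSchemeError(ValueError):
    """Raised when an SSC value falls outside every grade interval."""


@dataclass(frozen=True)
class GradeScheme:
    """Half-open °Brix intervals defining quality grades 1 (top) to 3 (poor).

    Defaults follow the 3-grade convention: Grade 1 = [14, 18),
    Grade 2 = [10, 14), Grade 3 = [8, 10). ``boundaries`` are the ordered
    cut points (low edge of Grade 3 up to the exclusive top of Grade 1).
    """

    boundaries: tuple[float, ...] = (8.0, 10.0, 14.0, 18.0)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("grade boundaries must be strictly increasing")

    @property
    def n_grades(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, ssc: float) -> int:
        return assign_grade(ssc, self)


def assign_grade(ssc: float, scheme: GradeScheme | None = None) -> int:
    """Map an SSC value (°Brix) to its grade under half-open intervals.

    Grade 1 is the top interval, grade numbers increase as quality drops.
    Raises :class:`OutOfSchemeError` for SSC outside the scheme rather than
    clamping, so synthetic sweeps cannot be silently corrupted.
    """
    if scheme is None:
        scheme = GradeScheme()
    ssc = float(ssc)
    if not np.isfinite(ssc):
        raise ValueError(f"SSC must be finite, got {ssc!r}")
    b = scheme.boundaries
    if ssc < b[0] or ssc >= b[-1]:
        raise OutOfSchemeError(
            f"SSC {ssc} °Brix outside the grading scheme [{b[0]}, {b[-1]})"
        )
    # intervals are ordered low->high; grade 1 is the highest interval
    for g in range(scheme.n_grades):
        lo, hi = b[-(g + 2)], b[-(g + 1)]
        if lo <= ssc < hi:
            return g + 1
    raise OutOfSchemeError(f"SSC {ssc} not covered by scheme {b}")  # pragma: no cover


def _grades_from_ssc(ssc: np.ndarray, scheme: GradeScheme) -> np.ndarray:
    """Vector grade assignment; NaN SSC (unlabelled sample) maps to grade 0."""
    return np.array(
        [0 if np.isnan(v) else assign_grade(v, scheme) for v in ssc], dtype=int
    )


@dataclass
class SpectrumSet:
    """Sample-by-wavelength absorbance matrix with optional SSC labels."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    ssc: np.ndarray | None = None
    grade: np.ndarray | None = None
    scheme: GradeScheme = field(default_factory=GradeScheme)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraFormatError("wavelengths must be a strictly increasing 1-D grid")
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise SpectraFormatError(
                f"absorbance has {p} columns but grid has {self.wavelengths.size} points"
            )
        if n != len(self.sample_ids):
            raise SpectraFormatError(
                f"{n} spectra but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraFormatError(f"duplicate sample id(s): {', '.join(dupes)}")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpectraFormatError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]}, "
                f"wavelength {self.wavelengths[bad[1]]:g} nm"
            )
        if self.ssc is not None:
            self.ssc = np.asarray(self.ssc, dtype=float)
            if self.ssc.shape != (n,):
                raise SpectraFormatError("ssc length must match sample count")
            if np.any(np.isinf(self.ssc)):
                raise SpectraFormatError("ssc values must be finite (NaN = unlabelled)")
        if self.grade is None and self.ssc is not None:
            self.grade = _grades_from_ssc(self.ssc, self.scheme)
        if self.grade is not None:
            self.grade = np.asarray(self.grade, dtype=int)
            if self.grade.shape != (n,):
                raise SpectraFormatError("grade length must match sample count")
            if self.ssc is not None:
                expect = _grades_from_ssc(self.ssc, self.scheme)
                if not np.array_equal(expect, self.grade):
                    raise SpectraFormatError("grades inconsistent with SSC under the scheme")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_absorbance(self, matrix: np.ndarray) -> "SpectrumSet":
        """Same samples and labels, new absorbance matrix (pretreatment output)."""
        return replace(self, absorbance=np.asarray(matrix, dtype=float))

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            ssc=None if self.ssc is None else self.ssc[idx],
            grade=None if self.grade is None else self.grade[idx],
            scheme=self.scheme,
        )


def read_spectra(
    spectra_path: str | Path,
    metadata_path: str | Path | None = None,
    scheme: GradeScheme | None = None,
) -> SpectrumSet:
    """Read a spectra CSV (header ``sample_id,400,405,...``) plus optional
    metadata CSV (``sample_id,ssc_brix``) into a validated SpectrumSet.

    Samples present in the spectra table but absent from the metadata carry
    no SSC (and then no grade).
    """
    df = pd.read_csv(spectra_path, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise SpectraFormatError("spectra CSV must start with a 'sample_id' column")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraFormatError("wavelength header is not strictly increasing")
    ids = df["sample_id"].tolist()
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise SpectraFormatError(f"duplicate sample id(s): {', '.join(map(str, dupes))}")
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(matrix)):
        r, c = np.argwhere(~np.isfinite(matrix))[0]
        raise SpectraFormatError(
            f"non-numeric cell at sample {ids[r]}, column {df.columns[c + 1]}"
        )

    ssc = None
    if metadata_path is not None:
        meta = pd.read_csv(
            metadata_path, dtype={"sample_id": str}, float_precision="round_trip"
        )
        if not {"sample_id", "ssc_brix"} <= set(meta.columns):
            raise SpectraFormatError("metadata CSV needs columns sample_id, ssc_brix")
        lookup = dict(zip(meta["sample_id"], meta["ssc_brix"].astype(float)))
        vals = [lookup.get(s, np.nan) for s in ids]
        if not all(np.isnan(v) for v in vals):
            ssc = np.array(vals)

    return SpectrumSet(wavelengths, matrix, ids, ssc=ssc, scheme=scheme or GradeScheme())


def write_spectra(
    data: SpectrumSet,
    spectra_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the spectra (and metadata, when SSC is present) as CSV."""
    df = pd.DataFrame(data.absorbance, columns=[f"{w:g}" for w in data.wavelengths])
    df.insert(0, "sample_id", data.sample_ids)
    df.to_csv(spectra_path, index=False)
    if metadata_path is not None and data.ssc is not None:
        pd.DataFrame({"sample_id": data.sample_ids, "ssc_brix": data.ssc}).to_csv(
            metadata_path, index=False
        )


def stratified_indices(
    grades: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Grade-stratified hold-out indices (train, test).

    Per-grade test counts are the nearest integer of fraction x grade size;
    any remainder against the global target count is absorbed by the largest
    grade so the overall ratio stays exact where possible. Deterministic for
    a fixed seed; the two index sets partition 0..n-1 with no overlap.
    """
    g_arr = np.asarray(grades, dtype=int)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.unique(g_arr)
    sizes = {g: int(np.sum(g_arr == g)) for g in labels}
    for g, s in sizes.items():
        if s < 2:
            raise ValueError(f"grade {g} has {s} sample(s); cannot stratify")
    counts = {g: int(round(test_fraction * s)) for g, s in sizes.items()}
    target = int(round(test_fraction * g_arr.size))
    diff = target - sum(counts.values())
    if diff:
        g_big = max(sizes, key=lambda g: sizes[g])
        counts[g_big] = int(np.clip(counts[g_big] + diff, 1, sizes[g_big] - 1))
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for g in labels:
        members = np.flatnonzero(g_arr == g)
        take = rng.permutation(members)[: counts[g]]
        test_idx.extend(take.tolist())
    test = np.array(sorted(test_idx), dtype=int)
    train = np.array(sorted(set(range(g_arr.size)) - set(test_idx)), dtype=int)
    return train, test


def stratified_split(
    data: SpectrumSet, test_fraction: float, seed: int
) -> tuple[SpectrumSet, SpectrumSet]:
    """Grade-stratified random hold-out split of a SpectrumSet (e.g. 8:2
    with fraction 0.2); see :func:`stratified_indices` for the rounding rule."""
    if data.grade is None or np.any(data.grade == 0):
        raise ValueError("stratified_split requires grades on every sample")
    train_idx, test_idx = stratified_indices(data.grade, test_fraction, seed)
    return data.subset(train_idx), data.subset(test_idx)
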