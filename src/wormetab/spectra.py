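"""Spectral preprocessing: I/O, water-region exclusion, adaptive binning,
probability quotient normalization (PQN) and mean-centering.

The processing order mirrors standard 1D 1H-NMR metabolomics practice:

1. read post-processed spectra (two-column ASCII: ppm, intensity) and put
   them on a common chemical-shift axis,
2. drop the residual-water region (default 4.70-5.25 ppm),
3. integrate into adaptive bins (default 0.2-8.8 ppm, ~0.015 ppm average
   width) whose boundaries sit in valleys of the smoothed mean spectrum,
4. PQN-normalize each sample to correct global dilution differences,
5. mean-center columns before multivariate modelling.

Axes are stored ascending internally; writers emit the conventional
descending-ppm order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.signal import find_peaks, savgol_filter

from .errors import InputError

WATER_REGION = (4.70, 5.25)


@dataclass
class Spectrum:
    """A single 1D spectrum on a strictly monotone ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise InputError(f"{self.sample_id}: ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise InputError(
                f"{self.sample_id}: axis length {self.ppm.size} != "
                f"intensity length {self.intensity.size}"
            )
        if not (np.isfinite(self.ppm).all() and np.isfinite(self.intensity).all()):
            raise InputError(f"{self.sample_id}: non-finite values present")
        d = np.diff(self.ppm)
        if (d > 0).all():
            pass
        elif (d < 0).all():  # descending input (NMR display order): store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise InputError(f"{self.sample_id}: ppm axis is not strictly monotone")


@dataclass
class SpectraSet:
    """Spectra on one shared ascending axis plus the sample manifest."""

    ppm: np.ndarray
    X: np.ndarray  # samples x points
    sample_ids: list[str]
    manifest: pd.DataFrame  # indexed by sample_id; at least a 'group' column
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), self.ppm.size):
            raise InputError("intensity matrix shape does not match axis/samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample_id in SpectraSet")
        missing = [s for s in self.sample_ids if s not in self.manifest.index]
        if missing:
            raise InputError(f"samples missing from manifest: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> pd.Series:
        return self.manifest.loc[self.sample_ids, "group"]

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum], manifest: pd.DataFrame) -> "SpectraSet":
        """Assemble a set, resampling onto the first spectrum's axis if needed.

        Resampling is linear interpolation; outside the source axis the
        intensity is taken as 0.
        """
        if not spectra:
            raise InputError("no spectra given")
        ids = [s.sample_id for s in spectra]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise InputError(f"duplicate sample_id: {sorted(dup)}")
        axis = spectra[0].ppm
        rows = []
        for s in spectra:
            if s.ppm.size == axis.size and np.array_equal(s.ppm, axis):
                rows.append(s.intensity)
            else:
                rows.append(np.interp(axis, s.ppm, s.intensity, left=0.0, right=0.0))
        return cls(axis.copy(), np.vstack(rows), ids, manifest)


def _parse_ascii_spectrum(path: str, sample_id: str) -> Spectrum:
    """Parse a two-column ASCII spectrum (whitespace or comma separated)."""
    try:
        arr = np.loadtxt(path, delimiter=None)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("need two columns")
        return Spectrum(arr[:, 0], arr[:, 1], sample_id)
    except OSError:
        raise InputError(f"spectrum file not found: {path}")
    except ValueError:
        pass
    # slow path: locate the offending line for the error message
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            txt = line.strip()
            if not txt or txt.startswith("#"):
                continue
            parts = txt.replace(",", " ").split()
            if len(parts) < 2:
                raise InputError(f"{path}, line {lineno}: expected two columns")
            try:
                float(parts[0]), float(parts[1])
            except ValueError:
                raise InputError(f"{path}, line {lineno}: non-numeric row {txt!r}")
    raise InputError(f"{path}: could not parse as two numeric columns")


def read_spectra(manifest_path: str) -> SpectraSet:
    """Read a sample manifest CSV and the spectra it references.

    The manifest needs columns ``sample_id``, ``group`` and ``file`` (path
    relative to the manifest's directory); extra columns such as ``dose`` or
    ``soil`` are carried along.
    """
    import os

    try:
        man = pd.read_csv(manifest_path)
    except OSError:
        raise InputError(f"manifest not found: {manifest_path}")
    for col in ("sample_id", "group", "file"):
        if col not in man.columns:
            raise InputError(f"{manifest_path}: manifest lacks column {col!r}")
    ids = man["sample_id"].astype(str).tolist()
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise InputError(f"{manifest_path}: duplicate sample_id {dups}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    spectra = []
    for _, row in man.iterrows():
        path = row["file"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        spectra.append(_parse_ascii_spectrum(path, str(row["sample_id"])))
    manifest = man.set_index(man["sample_id"].astype(str)).drop(columns=["sample_id"])
    return SpectraSet.from_spectra(spectra, manifest)


def write_spectra(ss: SpectraSet, out_dir: str) -> pd.DataFrame:
    """Write one two-column ASCII file per sample (descending ppm, NMR
    convention) plus ``manifest.csv``; returns the manifest written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    files = []
    for i, sid in enumerate(ss.sample_ids):
        fname = f"{sid}.txt"
        arr = np.column_stack([ss.ppm[::-1], ss.X[i, ::-1]])
        np.savetxt(os.path.join(out_dir, fname), arr, fmt="%.6f\t%.8e")
        files.append(fname)
    man = ss.manifest.loc[ss.sample_ids].copy()
    man.insert(0, "sample_id", ss.sample_ids)
    man["file"] = files
    man.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return man


def exclude_region(ss: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Drop all axis points with lo <= ppm <= hi (e.g. the water band)."""
    if not hi > lo:
        raise InputError(f"invalid exclusion region ({lo}, {hi}): need lo < hi")
    mask = (ss.ppm < lo) | (ss.ppm > hi)
    if mask.all():  # region outside the axis: nothing to do
        return ss
    if not mask.any():
        raise InputError(f"exclusion ({lo}, {hi}) would remove the entire axis")
    return SpectraSet(
        ss.ppm[mask],
        ss.X[:, mask],
        list(ss.sample_ids),
        ss.manifest,
        ss.excluded_regions + [(lo, hi)],
    )


# ---------------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class Bin:
    lo_ppm: float
    hi_ppm: float

    def __post_init__(self):
        if not self.hi_ppm > self.lo_ppm:
            raise InputError(f"bin ({self.lo_ppm}, {self.hi_ppm}): lo must be < hi")

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo_ppm + self.hi_ppm)

    @property
    def width(self) -> float:
        return self.hi_ppm - self.lo_ppm


@dataclass
class BinTable:
    """Sample x bin trapezoidal integrals plus the bin intervals."""

    bins: list[Bin]
    X: np.ndarray
    sample_ids: list[str]
    manifest: pd.DataFrame
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.mid for b in self.bins])

    def to_csv(self, path: str) -> None:
        _matrix_to_csv(path, self.bins, self.X, self.sample_ids)


def _matrix_to_csv(path, bins, X, sample_ids, extra_cols=None):
    """CSV layout: three header rows (bin lo / hi / midpoint), then samples."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lo_ppm"] + [f"{b.lo_ppm:.6f}" for b in bins])
        w.writerow(["hi_ppm"] + [f"{b.hi_ppm:.6f}" for b in bins])
        w.writerow(["sample_id\\mid_ppm"] + [f"{b.mid:.6f}" for b in bins])
        for i, sid in enumerate(sample_ids):
            row = [sid] + [repr(float(v)) for v in X[i]]
            if extra_cols:
                row += [repr(float(extra_cols[i]))]
            w.writerow(row)


def _segments(ppm: np.ndarray) -> list[slice]:
    """Contiguous runs of the axis, split where excluded regions left gaps."""
    dx = np.diff(ppm)
    step = np.median(dx)
    breaks = np.nonzero(dx > 3 * step)[0]
    out, start = [], 0
    for b in breaks:
        out.append(slice(start, b + 1))
        start = b + 1
    out.append(slice(start, ppm.size))
    return [s for s in out if s.stop - s.start >= 2]


def adaptive_bin(
    ss: SpectraSet,
    lo: float = 0.2,
    hi: float = 8.8,
    target_width: float = 0.015,
) -> BinTable:
    """Adaptively bin spectra between ``lo`` and ``hi`` ppm.

    Boundaries are placed at local minima of the Savitzky-Golay-smoothed
    mean spectrum (minimum spacing half the target width); stretches longer
    than twice the target width without a minimum are split uniformly so the
    average bin width stays near ``target_width``. Bin values are
    trapezoidal integrals over half-open intervals [lo_bin, hi_bin); because
    adjacent bins share their boundary grid point, the bins exactly tile the
    integral of each contiguous segment.
    """
    if ss.n_samples == 0:
        raise InputError("empty SpectraSet")
    if not (lo < hi and target_width > 0):
        raise InputError("need lo < hi and target_width > 0")
    sel = (ss.ppm >= lo) & (ss.ppm <= hi)
    if sel.sum() < 8:
        raise InputError(f"fewer than 8 axis points in [{lo}, {hi}]")
    ppm = ss.ppm[sel]
    X = ss.X[:, sel]
    mean_spec = X.mean(axis=0)

    bins: list[Bin] = []
    cols: list[np.ndarray] = []
    for seg in _segments(ppm):
        p = ppm[seg]
        m = mean_spec[seg]
        dx = np.median(np.diff(p))
        # smooth at roughly the bin-width scale before looking for valleys
        win = int(round(target_width / dx))
        win = max(5, win + (win + 1) % 2)  # odd, >= 5
        sm = savgol_filter(m, win, 2) if p.size > win else m
        min_dist = max(1, int(round(0.5 * target_width / dx)))
        minima, _ = find_peaks(-sm, distance=min_dist)
        bounds = [0] + [int(i) for i in minima] + [p.size - 1]
        bounds = sorted(set(bounds))
        # split long valley-free stretches uniformly
        refined = [bounds[0]]
        for a, b in zip(bounds[:-1], bounds[1:]):
            width = p[b] - p[a]
            if width > 2 * target_width:
                k = max(1, int(round(width / target_width)))
                inner = a + np.round(np.linspace(0, b - a, k + 1)).astype(int)[1:]
                refined.extend(int(i) for i in inner)
            else:
                refined.append(b)
        refined = sorted(set(refined))
        # merge bins narrower than half the target into the narrower neighbour
        widths = np.diff(p[refined])
        keep = list(refined)
        changed = True
        while changed and len(keep) > 2:
            changed = False
            widths = np.diff(p[keep])
            j = int(np.argmin(widths))
            if widths[j] < 0.5 * target_width:
                # drop the interior boundary adjoining the narrow bin
                drop = j + 1 if j + 1 < len(keep) - 1 else j
                if 0 < drop < len(keep) - 1:
                    del keep[drop]
                    changed = True
        # trapezoid cumulative integral per sample over this segment
        seg_X = X[:, seg]
        incr = 0.5 * (seg_X[:, 1:] + seg_X[:, :-1]) * np.diff(p)
        cumint = np.concatenate(
            [np.zeros((seg_X.shape[0], 1)), np.cumsum(incr, axis=1)], axis=1
        )
        for a, b in zip(keep[:-1], keep[1:]):
            bins.append(Bin(float(p[a]), float(p[b])))
            cols.append(cumint[:, b] - cumint[:, a])
    order = np.argsort([b.lo_ppm for b in bins])
    bins = [bins[i] for i in order]
    Xb = np.column_stack([cols[i] for i in order])
    return BinTable(bins, Xb, list(ss.sample_ids), ss.manifest, list(ss.excluded_regions))


# ---------------------------------------------------------------------------
# normalization / centering


@dataclass
class FeatureMatrix:
    """Normalized (optionally centered) sample x feature matrix."""

    X: np.ndarray
    bins: list[Bin]
    sample_ids: list[str]
    manifest: pd.DataFrame
    normalization_quotients: np.ndarray | None = None
    centered: bool = False
    column_means: np.ndarray | None = None

    @property
    def feature_ppm(self) -> np.ndarray:
        return np.array([b.mid for b in self.bins])

    def group_labels(self) -> np.ndarray:
        return self.manifest.loc[self.sample_ids, "group"].to_numpy()

    def to_csv(self, path: str) -> None:
        _matrix_to_csv(path, self.bins, self.X, self.sample_ids)

    @classmethod
    def from_csv(cls, path: str, manifest: pd.DataFrame | None = None) -> "FeatureMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        lo = [float(v) for v in rows[0][1:]]
        hi = [float(v) for v in rows[1][1:]]
        bins = [Bin(a, b) for a, b in zip(lo, hi)]
        ids = [r[0] for r in rows[3:]]
        X = np.array([[float(v) for v in r[1:]] for r in rows[3:]])
        if manifest is None:
            manifest = pd.DataFrame({"group": ["?"] * len(ids)}, index=ids)
        return cls(X, bins, ids, manifest)


def pqn_normalize(
    bt: BinTable, reference: str | tuple[str, str] = "median-of-all"
) -> FeatureMatrix:
    """Probability quotient normalization of a bin table.

    Each sample is first scaled to the reference spectrum's total integral,
    then divided by the median of its bin-wise ratios to the reference. The
    stored ``normalization_quotients`` are the combined per-sample divisors
    on the original scale, i.e. the estimated dilution factors.

    ``reference`` is ``"median-of-all"`` (bin-wise median over every sample,
    the method's default) or ``("median-of-group", label)``.
    """
    X = bt.X
    if isinstance(reference, tuple):
        mode, label = reference
        if mode != "median-of-group":
            raise InputError(f"unknown PQN reference {reference!r}")
        in_group = bt.manifest.loc[bt.sample_ids, "group"].to_numpy() == label
        if not in_group.any():
            raise InputError(f"PQN reference group {label!r} has no samples")
        ref = np.median(X[in_group], axis=0)
    elif reference == "median-of-all":
        ref = np.median(X, axis=0)
    else:
        raise InputError(f"unknown PQN reference {reference!r}")

    if (ref > 0).mean() < 0.5:
        raise InputError("PQN reference spectrum is not positive on >=50% of bins")
    totals = X.sum(axis=1)
    zero = [sid for sid, t in zip(bt.sample_ids, np.abs(X).sum(axis=1)) if t == 0]
    if zero:
        raise InputError(f"all-zero sample(s): {zero}")
    ref_total = ref.sum()
    # Bins where the reference sits at the noise floor cannot inform the
    # quotient (their ratios are arbitrary); the floor is estimated robustly
    # from the reference itself (MAD about the median, which for binned
    # spectra with many signal-free bins tracks the noise scale).
    mad = np.median(np.abs(ref - np.median(ref)))
    floor = max(5 * 1.4826 * mad, 1e-12 * ref.max())
    valid = ref > floor
    if valid.sum() < max(3, 0.05 * ref.size):
        valid = ref > 1e-12 * ref.max()
    quotients = np.empty(len(bt.sample_ids))
    Xn = np.empty_like(X)
    for i in range(X.shape[0]):
        scale = totals[i] / ref_total
        s1 = X[i] / scale
        q = float(np.median(s1[valid] / ref[valid]))
        if not q > 0:
            raise InputError(
                f"non-positive PQN quotient for sample {bt.sample_ids[i]!r}"
            )
        quotients[i] = scale * q
        Xn[i] = X[i] / quotients[i]
    return FeatureMatrix(
        Xn, list(bt.bins), list(bt.sample_ids), bt.manifest,
        normalization_quotients=quotients, centered=False,
    )


def mean_center(fm: FeatureMatrix) -> FeatureMatrix:
    """Subtract column means; the means are retained for back-transformation."""
    if fm.centered:
        raise InputError("FeatureMatrix is already centered")
    if fm.X.shape[0] < 2:
        raise InputError("cannot mean-center a single-sample matrix")
    means = fm.X.mean(axis=0)
    return replace(fm, X=fm.X - means, centered=True, column_means=means)


def total_integral(ss: SpectraSet, lo: float | None = None, hi: float | None = None):
    """Per-sample trapezoidal integral over [lo, hi] (whole axis by default)."""
    sel = np.ones(ss.ppm.size, bool)
    if lo is not None:
        sel &= ss.ppm >= lo
    if hi is not None:
        sel &= ss.ppm <= hi
    out = np.empty(ss.n_samples)
    ppm = ss.ppm[sel]
    for i in range(ss.n_samples):
        tot = 0.0
        for seg in _segments(ppm):
            tot += trapezoid(ss.X[i, sel][seg], ppm[seg])
        out[i] = tot
    return out
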