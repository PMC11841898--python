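"""Molecular-ladder sizing: assign ladder peaks to the fragment sizes of
a size standard, fit a scan→bp polynomial, and score the sizing quality.

The electrophoretic mobility of DNA fragments is a smooth, monotone but
non-linear function of length, so the local slope d(scan)/d(size)
between consecutive ladder fragments varies slowly.  The matcher
exploits exactly that: among all monotone matchings of detected peaks to
standard sizes it maximises

    bonus * k  -  sum |log slope(i,i+1) - log slope(i-1,i)|

i.e. a reward per matched fragment minus the total variation of the
log-slope along the matching.  Spurious peaks and missing fragments
break the smooth slope progression and are left unassigned.  The
optimum is found exactly by dynamic programming over matching "edges"
(consecutive matched pairs).

Sizing itself is an ordinary least-squares polynomial of degree 1-3,
size = f(scan at peak apex), solved by Cholesky decomposition of the
normal equations on centred/scaled scan numbers.

The quality score in [0, 1] penalises jumps in residuals between
adjacent ladder peaks (the signature of one mis-assigned fragment) and,
more mildly, standard sizes left without a peak:

    score = max(0, 1 - max(dR^2/dS) * 10/3 - (n_s - n_p)/10)

where dR is the residual difference and dS the scan difference of an
adjacent peak pair, n_s the number of sizes in the standard and n_p the
number of assigned peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import Polynomial
from scipy.linalg import cho_factor, cho_solve

from .signal import Peak

__all__ = [
    "SizeStandard",
    "SizingFit",
    "assign_ladder",
    "filter_unusual_height",
    "fit_sizing",
    "quality_score",
    "size_at_scan",
    "scan_at_size",
    "builtin_standards",
    "read_standard",
    "write_standard",
    "MATCH_BONUS",
]

#: reward per matched ladder fragment in the matcher's objective; a
#: candidate assignment is only worth making when it costs less than
#: this in log-slope distortion
MATCH_BONUS = 0.5

#: residual window (bp) for the post-fit refinement re-match
REFINE_WINDOW_BP = 2.0


@dataclass(frozen=True)
class SizeStandard:
    """A named ladder: strictly increasing fragment sizes in base pairs."""

    name: str
    sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) < 4:
            raise ValueError("size standard needs at least 4 sizes")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("size standard sizes must be strictly increasing")


@dataclass
class SizingFit:
    """A fitted scan→bp calibration for one sample.

    ``coefficients`` are ascending-power polynomial coefficients in raw
    scan units; ``assignments`` the (peak, standard size) pairs used;
    ``residuals`` the per-assignment difference between the standard
    size and the model prediction at the peak apex.
    """

    degree: int
    coefficients: np.ndarray
    assignments: list[tuple[Peak, float]]
    residuals: np.ndarray
    quality: float = field(default=float("nan"))

    @property
    def n_points(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# ladder assignment

def filter_unusual_height(
    peaks: list[Peak], low_factor: float = 0.1, high_factor: float = 10.0
) -> list[Peak]:
    """Drop peaks whose height is unusual relative to the median.

    Ladder fragments are loaded at comparable molarity, so their peaks
    have comparable heights; a peak far outside
    ``[median*low_factor, median*high_factor]`` is an artifact.
    """
    if not peaks:
        raise ValueError("no peaks to filter")
    med = float(np.median([p.height for p in peaks]))
    return [p for p in peaks if med * low_factor <= p.height <= med * high_factor]


def matching_score(
    scans: np.ndarray, sizes: np.ndarray, bonus: float = MATCH_BONUS
) -> float:
    """Objective value of one monotone matching (scans[i] <-> sizes[i])."""
    k = len(scans)
    total = bonus * k
    slopes = [
        math.log((scans[i + 1] - scans[i]) / (sizes[i + 1] - sizes[i]))
        for i in range(k - 1)
    ]
    total -= sum(abs(b - a) for a, b in zip(slopes, slopes[1:]))
    return total


def _dp_match(
    scans: np.ndarray, sizes: np.ndarray, bonus: float
) -> list[tuple[int, int]]:
    """Exact optimum of the matching objective via edge-DP.

    State = the last two matched (peak, size) pairs; the transition cost
    |log slope(prev edge) - log slope(next edge)| only couples adjacent
    edges, so the DP over edges is exact.  Complexity is the number of
    increasing pair-triples, vectorised per middle pair.
    """
    n_p, n_s = len(scans), len(sizes)
    pair_i, pair_j = np.meshgrid(np.arange(n_p), np.arange(n_s), indexing="ij")
    pi = pair_i.ravel()
    pj = pair_j.ravel()
    n_pairs = n_p * n_s
    pscan = scans[pi].astype(float)
    psize = sizes[pj].astype(float)

    NEG = -np.inf
    D = np.full((n_pairs, n_pairs), NEG)
    parent = np.full((n_pairs, n_pairs), -1, dtype=np.int32)
    # strictly increasing in peak index, size index AND scan (co-eluting
    # peaks cannot both be ladder fragments of different sizes)
    increasing = (
        (pi[:, None] < pi[None, :])
        & (pj[:, None] < pj[None, :])
        & (pscan[:, None] < pscan[None, :])
    )
    D[increasing] = 2.0 * bonus  # any single edge = two matched pairs

    order = np.lexsort((pj, pi))
    for b in order:
        inc = np.flatnonzero(increasing[:, b])
        out = np.flatnonzero(increasing[b, :])
        if inc.size == 0 or out.size == 0:
            continue
        v = np.log((pscan[b] - pscan[inc]) / (psize[b] - psize[inc]))
        u = np.log((pscan[out] - pscan[b]) / (psize[out] - psize[b]))
        cand = D[inc, b][:, None] + bonus - np.abs(u[None, :] - v[:, None])
        best = cand.max(axis=0)
        arg = cand.argmax(axis=0)
        improve = best > D[b, out]
        D[b, out[improve]] = best[improve]
        parent[b, out[improve]] = inc[arg[improve]]

    flat = np.argmax(D)
    a, b = np.unravel_index(flat, D.shape)
    if not np.isfinite(D[a, b]):
        # no valid edge: match the single best... degenerate, return empty
        return []
    chain = [b, a]
    while parent[chain[-1], chain[-2]] >= 0:
        chain.append(int(parent[chain[-1], chain[-2]]))
    chain.reverse()
    return [(int(pi[p]), int(pj[p])) for p in chain]


def _refine(
    peaks: list[Peak],
    standard: SizeStandard,
    matches: list[tuple[int, int]],
    window_bp: float = REFINE_WINDOW_BP,
) -> list[tuple[int, int]]:
    """One refinement pass: fit, then re-match peaks within a residual window.

    Alignment DP maximising the number of matches with |predicted size -
    standard size| <= window, breaking ties toward minimal total
    deviation.
    """
    if len(matches) < 2:
        return matches
    degree = min(3, len(matches) - 1)
    assignments = [(peaks[i], standard.sizes[j]) for i, j in matches]
    try:
        fit = fit_sizing(assignments, degree=degree)
    except ValueError:
        return matches
    pred = np.array([size_at_scan(fit, p.apex_scan) for p in peaks])
    sizes = np.asarray(standard.sizes)
    n_p, n_s = len(peaks), len(sizes)
    cost = np.abs(pred[:, None] - sizes[None, :])
    feasible = cost <= window_bp
    # DP: maximise matches, then minimise cost
    best = np.zeros((n_p + 1, n_s + 1))
    cum = np.zeros((n_p + 1, n_s + 1))
    back = np.zeros((n_p + 1, n_s + 1), dtype=np.int8)  # 0=skip peak,1=skip size,2=match
    for i in range(1, n_p + 1):
        for j in range(1, n_s + 1):
            options = [(best[i - 1][j], cum[i - 1][j], 0), (best[i][j - 1], cum[i][j - 1], 1)]
            if feasible[i - 1, j - 1]:
                options.append(
                    (best[i - 1][j - 1] + 1, cum[i - 1][j - 1] + cost[i - 1, j - 1], 2)
                )
            b, c, k = max(options, key=lambda t: (t[0], -t[1]))
            best[i][j], cum[i][j], back[i][j] = b, c, k
    out: list[tuple[int, int]] = []
    i, j = n_p, n_s
    while i > 0 and j > 0:
        k = back[i][j]
        if k == 2:
            out.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif k == 0:
            i -= 1
        else:
            j -= 1
    out.reverse()
    # the residual window may orphan matches the optimiser made at the
    # extremes, where polynomial lack-of-fit is largest; restore any
    # original match whose peak and size both remain free, provided the
    # matching stays monotone
    used_p = {i for i, _ in out}
    used_s = {j for _, j in out}
    for i, j in matches:
        if i in used_p or j in used_s:
            continue
        trial = sorted(out + [(i, j)])
        if all(a[0] < b[0] and a[1] < b[1] for a, b in zip(trial, trial[1:])):
            out = trial
            used_p.add(i)
            used_s.add(j)
    return out


def assign_ladder(
    peaks: list[Peak],
    standard: SizeStandard,
    bonus: float = MATCH_BONUS,
    refine: bool = True,
) -> list[tuple[Peak, float]]:
    """Match ladder-channel peaks to the standard's fragment sizes.

    ``peaks`` should already exclude crosstalk-flagged and
    unusual-height peaks.  Returns (peak, size) pairs strictly
    increasing in both scan and size; artifact peaks and missing
    fragments remain unassigned.  Raises ``ValueError`` when fewer than
    4 usable peaks are available.
    """
    usable = sorted(
        (p for p in peaks if not p.crosstalk), key=lambda p: p.apex_scan
    )
    if len(usable) < 4:
        raise ValueError(
            f"insufficient ladder peaks: {len(usable)} usable, need >= 4"
        )
    scans = np.array([p.apex_scan for p in usable], dtype=float)
    sizes = np.array(standard.sizes, dtype=float)
    matches = _dp_match(scans, sizes, bonus)
    if refine:
        matches = _refine(usable, standard, matches)
    return [(usable[i], float(standard.sizes[j])) for i, j in matches]


# ---------------------------------------------------------------------------
# polynomial fit

def fit_sizing(assignments: list[tuple[Peak, float]], degree: int = 3) -> SizingFit:
    """Least-squares polynomial size = f(apex scan) of degree 1, 2 or 3.

    Solved by Cholesky decomposition of the normal equations; scans are
    centred and scaled to [-1, 1] first because normal equations on raw
    scan numbers (~1e4) of degree 3 are hopelessly ill-conditioned.
    Coefficients are reported in raw scan units (ascending powers).
    """
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    if len(assignments) < degree + 1:
        raise ValueError(
            f"degree exceeds data: {len(assignments)} points for degree {degree}"
        )
    scans = np.array([p.apex_scan for p, _ in assignments], dtype=float)
    sizes = np.array([s for _, s in assignments], dtype=float)
    if np.unique(scans).size < degree + 1:
        raise ValueError("singular fit: duplicate scan numbers")
    lo, hi = scans.min(), scans.max()
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    t = (scans - mid) / half
    V = np.vander(t, degree + 1, increasing=True)
    A = V.T @ V
    rhs = V.T @ sizes
    try:
        coef_t = cho_solve(cho_factor(A), rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError("singular fit") from exc
    poly_t = Polynomial(coef_t, domain=[lo, hi], window=[-1.0, 1.0])
    coefficients = poly_t.convert(domain=[-1.0, 1.0], window=[-1.0, 1.0]).coef
    if coefficients.size < degree + 1:
        coefficients = np.pad(coefficients, (0, degree + 1 - coefficients.size))
    predicted = np.polynomial.polynomial.polyval(scans, coefficients)
    residuals = sizes - predicted
    return SizingFit(
        degree=degree,
        coefficients=coefficients,
        assignments=list(assignments),
        residuals=residuals,
    )


def size_at_scan(fit: SizingFit, scan) -> float:
    """Evaluate the fitted polynomial at a scan number (bp)."""
    val = np.polynomial.polynomial.polyval(np.asarray(scan, dtype=float),
                                           fit.coefficients)
    return float(val) if np.ndim(scan) == 0 else val


def scan_at_size(fit: SizingFit, size: float) -> float:
    """Invert the calibration numerically (used for display windows)."""
    coef = fit.coefficients.copy()
    coef[0] -= size
    roots = np.polynomial.polynomial.polyroots(coef)
    scans = np.array([p.apex_scan for p, _ in fit.assignments], dtype=float)
    lo, hi = scans.min() - 500, scans.max() + 500
    real = [r.real for r in roots if abs(r.imag) < 1e-6 and lo <= r.real <= hi]
    if not real:
        real = [r.real for r in roots if abs(r.imag) < 1e-6]
    if not real:
        raise ValueError("calibration not invertible at this size")
    return float(min(real, key=lambda r: abs(r - (lo + hi) / 2)))


def quality_score(fit: SizingFit, standard: SizeStandard) -> float:
    """Sizing quality in [0, 1] from residual jumps and missing fragments.

    score = max(0, 1 - max(dR^2 / dS) * 10/3 - (n_s - n_p)/10), where
    dR/dS are the residual/scan differences of adjacent assigned peaks.
    The 10/3 weight drives the score toward zero on a single
    mis-assignment; the 1/10 weight mildly penalises unassigned standard
    sizes (an electrophoresis problem the software cannot fix).  Fits
    with fewer than two assignments score 0.
    """
    n_p = fit.n_points
    n_s = len(standard.sizes)
    if n_p < 2:
        return 0.0
    scans = np.array([p.apex_scan for p, _ in fit.assignments], dtype=float)
    res = np.asarray(fit.residuals, dtype=float)
    dR = np.diff(res)
    dS = np.diff(scans)
    max_term = float(np.max(dR**2 / dS))
    score = 1.0 - max_term * (10.0 / 3.0) - (n_s - n_p) / 10.0
    return min(1.0, max(0.0, score))


def size_ladder(
    peaks: list[Peak], standard: SizeStandard, degree: int = 3
) -> SizingFit:
    """Full ladder workflow: filter, assign, fit, score, annotate sizes."""
    kept = filter_unusual_height([p for p in peaks if not p.crosstalk])
    assignments = assign_ladder(kept, standard)
    fit = fit_sizing(assignments, degree=degree)
    fit.quality = quality_score(fit, standard)
    return fit


# ---------------------------------------------------------------------------
# built-in standards and the text format

_BUILTINS: dict[str, tuple[float, ...]] = {
    "GeneScan-350": (35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350),
    "GeneScan-400HD": (
        50, 60, 90, 100, 120, 150, 160, 180, 190, 200, 220, 240,
        260, 280, 290, 300, 320, 340, 360, 380, 400,
    ),
    "GeneScan-500": (
        35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350,
        400, 450, 490, 500,
    ),
    "GeneScan-600": (
        20, 40, 60, 80, 100, 114, 120, 140, 160, 180, 200, 214, 220,
        240, 250, 260, 280, 300, 314, 320, 340, 360, 380, 400, 414,
        420, 440, 460, 480, 500, 514, 520, 540, 560, 580, 600,
    ),
}


def builtin_standards() -> list[SizeStandard]:
    """The widely used GeneScan-brand ladders shipped with the package."""
    return [SizeStandard(name, sizes) for name, sizes in _BUILTINS.items()]


def get_standard(name_or_path: str) -> SizeStandard:
    """Resolve a size standard by built-in name or by text-file path."""
    for std in builtin_standards():
        if std.name == name_or_path:
            return std
    path = Path(name_or_path)
    if path.exists():
        return read_standard(path)
    raise KeyError(f"unknown size standard: {name_or_path}")


def read_standard(path: str | Path) -> SizeStandard:
    """Read a standard from 2-column text: a 'name' header, then one size per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].lower().startswith("name"):
        raise ValueError("size standard file must start with a 'name' header line")
    parts = lines[0].split("\t")
    name = parts[1] if len(parts) > 1 else Path(path).stem
    sizes = tuple(float(ln) for ln in lines[1:])
    return SizeStandard(name, sizes)


def write_standard(standard: SizeStandard, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"name\t{standard.name}\n")
        for s in standard.sizes:
            fh.write(f"{s:g}\n")
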