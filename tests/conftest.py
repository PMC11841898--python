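"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import datetime
import math
from itertools import combinations

import numpy as np
import pytest

from msatcall.abif import Chromatogram
from msatcall.signal import Peak


# ---------------------------------------------------------------------------
# trace construction helpers

def gaussian_trace(n_scans: int, peaks, baseline: float = 0.0, sigma: float = 4.0):
    """A float trace with Gaussian bumps at (scan, height) positions."""
    x = np.arange(n_scans, dtype=float)
    trace = np.full(n_scans, float(baseline))
    for scan, height in peaks:
        trace += height * np.exp(-0.5 * ((x - scan) / sigma) ** 2)
    return np.rint(trace).astype(np.int64)


def random_chromatogram(rng: np.random.Generator) -> Chromatogram:
    """A random, valid multi-channel chromatogram for round-trip tests."""
    n_channels = int(rng.integers(4, 6))
    n_scans = int(rng.integers(50, 400))
    channels = [
        rng.integers(0, 32000, size=n_scans).astype(np.int64)
        for _ in range(n_channels)
    ]
    n_sat = int(rng.integers(0, 3))
    regions = []
    for _ in range(n_sat):
        c = int(rng.integers(0, n_channels))
        # slot-aligned starts keep regions disjoint within a channel
        s = int(rng.integers(0, (n_scans - 6) // 10)) * 10
        e = s + int(rng.integers(3, 5))
        if not any(r[0] == c and r[1] == s for r in regions):
            regions.append((c, s, min(e, n_scans)))
    return Chromatogram(
        sample_name=f"s{rng.integers(0, 10 ** 6)}",
        plate_name=f"plate{rng.integers(0, 100)}",
        well=f"{chr(ord('A') + int(rng.integers(0, 8)))}{int(rng.integers(1, 13)):02d}",
        run_date=datetime.date(2024, int(rng.integers(1, 13)), int(rng.integers(1, 29))),
        dye_names=[f"DYE{i}" for i in range(n_channels)],
        channels=channels,
        saturation_regions=sorted(set(regions)),
    )


def make_peak(scan: int, height: float = 1000.0, channel: int = 0,
              size: float | None = None, **kw) -> Peak:
    return Peak(
        channel=channel,
        start_scan=scan - 5,
        apex_scan=scan,
        end_scan=scan + 5,
        height=height,
        area=height * 5,
        size=size,
        **kw,
    )


# ---------------------------------------------------------------------------
# independent oracles for the ladder matcher
#
# Both optimise the same objective as the production matcher —
# bonus per matched pair minus the total variation of the log of the
# local scan-per-bp slope — but by different means: full enumeration
# for tiny instances, and a plain-Python suffix recursion for realistic
# ones.  Scoring is reimplemented here from the definition.

def _oracle_score(scans, sizes, bonus: float) -> float:
    k = len(scans)
    total = bonus * k
    slopes = []
    for i in range(k - 1):
        if scans[i + 1] <= scans[i]:
            return -math.inf  # co-eluting peaks cannot both be matched
        slopes.append(math.log((scans[i + 1] - scans[i]) / (sizes[i + 1] - sizes[i])))
    for a, b in zip(slopes, slopes[1:]):
        total -= abs(b - a)
    return total


def exhaustive_best_matching(scans, sizes, bonus: float):
    """Optimal monotone matching by full enumeration (tiny instances only)."""
    n_p, n_s = len(scans), len(sizes)
    best_score, best = 0.0, []
    for k in range(1, min(n_p, n_s) + 1):
        for ps in combinations(range(n_p), k):
            for ss in combinations(range(n_s), k):
                sc = _oracle_score([scans[i] for i in ps],
                                   [sizes[j] for j in ss], bonus)
                if sc > best_score:
                    best_score, best = sc, list(zip(ps, ss))
    return best_score, best


def suffix_dp_best_score(scans, sizes, bonus: float) -> float:
    """Optimal matching score via an independent suffix recursion.

    Processes candidate (peak, size) pairs in reverse lexicographic
    order; suffix[(a, b)] is the best score attainable by extending a
    matching whose last two pairs are a then b (excluding their own
    bonuses).
    """
    n_p, n_s = len(scans), len(sizes)
    pairs = [(i, j) for i in range(n_p) for j in range(n_s)]
    pairs.sort(reverse=True)
    succ = {
        p: [
            q for q in pairs
            if q[0] > p[0] and q[1] > p[1] and scans[q[0]] > scans[p[0]]
        ]
        for p in pairs
    }
    slope = {
        (p, q): math.log((scans[q[0]] - scans[p[0]]) / (sizes[q[1]] - sizes[p[1]]))
        for p in pairs
        for q in succ[p]
    }
    suffix: dict[tuple, float] = {}
    best = 0.0
    for p in pairs:
        for q in succ[p]:
            edge_slope = slope[(p, q)]
            ext = 0.0
            for r in succ[q]:
                cand = bonus - abs(slope[(q, r)] - edge_slope) + suffix[(q, r)]
                if cand > ext:
                    ext = cand
            suffix[(p, q)] = ext
            total = 2.0 * bonus + ext
            if total > best:
                best = total
    if pairs:
        best = max(best, bonus)  # a single matched pair
    return best


# ---------------------------------------------------------------------------
# synthetic ladder instances (peak-level, for matcher tests)

def make_ladder_instance(
    rng: np.random.Generator,
    sizes,
    n_spurious: int = 0,
    n_missing: int = 0,
    jitter_scans: float = 0.0,
):
    """Ladder peaks placed by a random monotone cubic mobility map.

    Returns (peaks, truth) where truth maps each genuine peak's index in
    ``peaks`` to its standard size; spurious peaks are absent from
    truth.  Peak heights are comparable (the matcher, not the height
    filter, is under test).
    """
    from msatcall.synth import mobility_scan, random_mobility_map

    coef = random_mobility_map(rng)
    sizes = list(sizes)
    present = sorted(
        rng.choice(len(sizes), size=len(sizes) - n_missing, replace=False)
    )
    entries = []
    for idx in present:
        scan = float(mobility_scan(coef, sizes[idx]))
        if jitter_scans:
            scan += rng.normal(0.0, jitter_scans)
        entries.append((scan, sizes[idx]))
    lo = mobility_scan(coef, sizes[0])
    hi = mobility_scan(coef, sizes[-1])
    for _ in range(n_spurious):
        entries.append((float(rng.uniform(lo + 10, hi - 10)), None))
    entries.sort(key=lambda t: t[0])
    peaks, truth = [], {}
    for i, (scan, size) in enumerate(entries):
        peaks.append(make_peak(int(round(scan)),
                               height=float(rng.uniform(800, 1200))))
        if size is not None:
            truth[i] = float(size)
    return peaks, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
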