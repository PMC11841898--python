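"""Synthetic chromatogram generation.

Emulates the signal phenomena a capillary sequencer produces —
Gaussian-ish fluorescence peaks placed by a monotone cubic size→scan
mobility map, stutter series, partial-adenylation peak splitting,
inter-channel crosstalk bleed, baseline fluorescence, Gaussian noise and
camera saturation (clipping) — with a ground-truth record of every
injected peak.  Every other module is testable against this generator
with no external data; see the methods note for what it deliberately
does not model.

Allele size convention: an allele's nominal size is the fully
adenylated (+A) product; partial adenylation places the remaining
fraction of the signal 1 bp below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .abif import SHORT_MAX, Chromatogram
from .panels import Marker, Panel
from .sizing import SizeStandard, get_standard

__all__ = [
    "SynthSpec",
    "TruthPeak",
    "TruthRecord",
    "default_panel",
    "default_mobility",
    "random_mobility_map",
    "generate_chromatogram",
    "generate_plate",
]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for synthetic data generation.

    ``mobility_map`` holds ascending-power cubic coefficients mapping
    fragment size (bp) to scan number, strictly increasing over the
    standard's range.  Heights are fluorescence units; ``stutter_ratio``
    is the per-repeat-step height decay, ``adenylation_split`` the
    fraction of fully adenylated (+A) product, ``crosstalk_bleed`` the
    fraction of each channel leaking into every other channel.
    """

    seed: int = 0
    standard: SizeStandard = None  # type: ignore[assignment]
    markers: tuple[Marker, ...] = ()
    mobility_map: tuple[float, ...] = None  # type: ignore[assignment]
    ladder_channel: int = 4
    n_channels: int = 5
    stutter_ratio: float = 0.3
    stutter_steps: int = 3
    adenylation_split: float = 0.6
    crosstalk_bleed: float = 0.05
    noise_sd: float = 10.0
    baseline_level: float = 30.0
    saturation_limit: float = 32000.0
    peak_sigma: float = 4.0
    ladder_height: float = 800.0
    allele_height_range: tuple[float, float] = (1500.0, 4000.0)
    het_balance_range: tuple[float, float] = (0.7, 1.0)
    min_fluorescence_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.standard is None:
            object.__setattr__(self, "standard", get_standard("GeneScan-500"))
        if not self.markers:
            object.__setattr__(self, "markers", tuple(default_panel().markers))
        if self.mobility_map is None:
            object.__setattr__(self, "mobility_map", default_mobility())
        for frac in (self.stutter_ratio, self.adenylation_split, self.crosstalk_bleed):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class TruthPeak:
    channel: int
    size: float
    scan: float
    height: float
    kind: str  # ladder | allele | stutter | non-adenylated


@dataclass
class TruthRecord:
    """Ground truth for one generated chromatogram."""

    sample: str
    genotypes: dict[str, tuple[float, ...]]  # marker name -> true allele sizes
    peaks: list[TruthPeak] = field(default_factory=list)
    drift: tuple[float, float] = (0.0, 1.0)  # (a, b): true = a + b * apparent


def default_panel() -> Panel:
    """A 4-marker multiplex spanning the four sample channels, each with
    a 1-bp bin set on its repeat grid."""
    from .panels import make_bin_set

    markers = [
        Marker("Ma", channel=0, ploidy=2, motif_length=2,
               range_start=248, range_end=272),
        Marker("Mb", channel=1, ploidy=2, motif_length=4,
               range_start=100, range_end=148),
        Marker("Mc", channel=2, ploidy=2, motif_length=2,
               range_start=180, range_end=210),
        Marker("Md", channel=3, ploidy=1, motif_length=3,
               range_start=300, range_end=330),
    ]
    for m in markers:
        m.bins = make_bin_set(m, width=1.0, spacing=float(m.motif_length),
                              anchor=m.range_start + m.motif_length)
    return Panel(name="synthetic-multiplex", markers=markers)


def default_mobility() -> tuple[float, float, float, float]:
    """A gently non-linear size→scan map, ~18 scans per bp.

    At sigma = 4 scans this reproduces the resolution of a capillary
    instrument: 1-bp-apart adenylation products appear as distinct,
    partially overlapping peaks.
    """
    return (150.0, 18.0, 4e-4, 2.4e-7)


def random_mobility_map(
    rng: np.random.Generator,
    size_range: tuple[float, float] = (30.0, 510.0),
    scan_range: tuple[float, float] = (800.0, 9500.0),
) -> tuple[float, float, float, float]:
    """Draw a random strictly increasing cubic size→scan map.

    The derivative is a positive quadratic 1 + alpha*s + beta*s^2 with
    alpha, beta >= 0, integrated and rescaled so the size range maps
    onto the scan range — monotone by construction.
    """
    alpha = rng.uniform(0.0, 4e-3)
    beta = rng.uniform(0.0, 4e-6)
    s0, s1 = size_range
    c_raw = np.array([0.0, 1.0, alpha / 2.0, beta / 3.0])
    u0 = np.polynomial.polynomial.polyval(s0, c_raw)
    u1 = np.polynomial.polynomial.polyval(s1, c_raw)
    lo, hi = scan_range
    scale = (hi - lo) / (u1 - u0)
    coef = c_raw * scale
    coef[0] = lo - u0 * scale
    return tuple(coef)


def mobility_scan(spec_or_coef, size) -> np.ndarray | float:
    coef = (
        spec_or_coef.mobility_map
        if isinstance(spec_or_coef, SynthSpec)
        else spec_or_coef
    )
    return np.polynomial.polynomial.polyval(np.asarray(size, dtype=float),
                                            np.asarray(coef))


def _add_gaussian(trace: np.ndarray, scan: float, height: float, sigma: float) -> None:
    lo = max(0, int(scan - 6 * sigma))
    hi = min(trace.size, int(scan + 6 * sigma) + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    trace[lo:hi] += height * np.exp(-0.5 * ((x - scan) / sigma) ** 2)


def _allele_products(
    size: float, height: float, spec: SynthSpec, motif: int
) -> list[tuple[float, float, str]]:
    """(size, height, kind) for one allele: stutter series x adenylation split."""
    out = []
    for k in range(spec.stutter_steps + 1):
        s = size - k * motif
        h = height * spec.stutter_ratio**k
        kind = "allele" if k == 0 else "stutter"
        if spec.adenylation_split >= 1.0:
            out.append((s, h, kind))
        elif spec.adenylation_split <= 0.0:
            out.append((s - 1.0, h, "non-adenylated" if k == 0 else "stutter"))
        else:
            out.append((s, h * spec.adenylation_split, kind))
            out.append((s - 1.0, h * (1.0 - spec.adenylation_split),
                        "non-adenylated" if k == 0 else "stutter"))
    return out


def generate_chromatogram(
    spec: SynthSpec,
    true_genotypes: dict[str, tuple[float, ...]],
    sample: str = "synthetic",
    heights: dict[str, tuple[float, ...]] | None = None,
    drift: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
    well: str = "A01",
    plate: str = "synthplate",
) -> tuple[Chromatogram, TruthRecord]:
    """Build one chromatogram plus its ground-truth record.

    ``true_genotypes`` maps marker names to allele sizes (within the
    marker range).  ``drift`` = (a, b) models between-run electrophoresis
    variation: a fragment whose true size is y migrates as if its size
    were x = (y - a) / b, so the offset correction y = a + b*x recovers
    the truth.  With ``rng`` omitted, output is a deterministic function
    of ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    markers = {m.name: m for m in spec.markers}
    for name, alleles in true_genotypes.items():
        m = markers[name]
        for a in alleles:
            if not m.range_start <= a <= m.range_end:
                raise ValueError(
                    f"allele {a} bp outside range of marker '{name}'"
                )

    a_dr, b_dr = drift
    max_size = max(spec.standard.sizes)
    n_scans = int(mobility_scan(spec, max_size) + 60 * spec.peak_sigma)
    clean = np.zeros((spec.n_channels, n_scans))
    truth = TruthRecord(sample=sample, genotypes=dict(true_genotypes), drift=drift)

    for size in spec.standard.sizes:
        scan = float(mobility_scan(spec, size))
        _add_gaussian(clean[spec.ladder_channel], scan, spec.ladder_height,
                      spec.peak_sigma)
        truth.peaks.append(TruthPeak(spec.ladder_channel, size, scan,
                                     spec.ladder_height, "ladder"))

    for name, alleles in true_genotypes.items():
        m = markers[name]
        hts = (heights or {}).get(name)
        if hts is None:
            # amplification strength is a property of the sample+locus;
            # heterozygote peaks are near-balanced, not independent
            base = rng.uniform(*spec.allele_height_range)
            hts = tuple(
                base * (1.0 if i == 0 else rng.uniform(*spec.het_balance_range))
                for i in range(len(alleles))
            )
        for i, allele in enumerate(alleles):
            h = hts[i]
            for psize, pheight, kind in _allele_products(allele, h, spec,
                                                         m.motif_length):
                apparent = (psize - a_dr) / b_dr
                scan = float(mobility_scan(spec, apparent))
                _add_gaussian(clean[m.channel], scan, pheight, spec.peak_sigma)
                truth.peaks.append(TruthPeak(m.channel, psize, scan, pheight, kind))

    if spec.crosstalk_bleed > 0:
        total = clean.sum(axis=0)
        bled = clean + spec.crosstalk_bleed * (total[None, :] - clean)
    else:
        bled = clean
    signal = bled + spec.baseline_level
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    signal = np.clip(signal, spec.min_fluorescence_floor,
                     min(spec.saturation_limit, SHORT_MAX))
    channels = [np.rint(signal[c]).astype(np.int64)
                for c in range(spec.n_channels)]
    chrom = Chromatogram(
        sample_name=sample,
        plate_name=plate,
        well=well,
        run_date=None,
        dye_names=[f"DYE{c + 1}" for c in range(spec.n_channels)],
        channels=channels,
    )
    from .abif import _detect_saturation

    chrom.saturation_regions = _detect_saturation(channels)
    return chrom, truth


def _draw_genotype(
    rng: np.random.Generator, marker: Marker,
    freqs: list[tuple[float, float]] | None,
) -> tuple[float, ...]:
    if freqs is None:
        # keep a motif-length margin at both ends: marker ranges are
        # defined with headroom around the observed alleles, and the +A
        # product of a boundary allele must stay inside the range
        start = marker.range_start + marker.motif_length
        stop = marker.range_end - marker.motif_length
        n_alleles = int((stop - start) // marker.motif_length)
        sizes = [start + k * marker.motif_length for k in range(n_alleles + 1)]
        probs = np.full(len(sizes), 1.0 / len(sizes))
    else:
        sizes = [s for s, _ in freqs]
        probs = np.array([f for _, f in freqs], dtype=float)
        probs = probs / probs.sum()
    draws = rng.choice(len(sizes), size=marker.ploidy, p=probs)
    return tuple(sorted(float(sizes[i]) for i in draws))


def random_genotype_peaks(
    rng: np.random.Generator,
    marker: Marker,
    stutter_ratio: float = 0.3,
    stutter_steps: int = 2,
    adenylation_split: float = 0.6,
    size_jitter: float = 0.05,
    spurious_rate: float = 0.7,
    crosstalk_rate: float = 0.3,
    saturation_rate: float = 0.05,
) -> tuple[list, tuple[float, ...]]:
    """Peak-level synthetic calling scenario for one marker.

    Skips the trace entirely: returns already-sized ``Peak`` objects the
    way the detector would deliver them — allele peaks with stutter
    series and adenylation splits (co-located products merged), spurious
    small peaks, occasional crosstalk-flagged peaks and saturated
    apexes — plus the true allele sizes.  Used to exercise clustering
    and calling at volumes where full trace synthesis is unnecessary.
    """
    from .signal import Peak

    grid_start = marker.range_start + marker.motif_length
    grid_stop = marker.range_end - marker.motif_length
    n = int((grid_stop - grid_start) // marker.motif_length) + 1
    grid = [grid_start + k * marker.motif_length for k in range(n)]
    alleles = tuple(sorted(
        float(grid[i]) for i in rng.choice(n, size=marker.ploidy)
    ))
    base = rng.uniform(1500.0, 4000.0)
    heights = [base] + [base * rng.uniform(0.7, 1.0)] * (marker.ploidy - 1)

    products: dict[float, float] = {}

    def add(size: float, height: float) -> None:
        if size < marker.range_start or size > marker.range_end:
            return
        for existing in list(products):
            if abs(existing - size) < 0.3:  # co-located products merge
                products[existing] += height
                return
        products[size] = height

    for allele, h in zip(dict.fromkeys(alleles), heights):
        mult = alleles.count(allele)
        for k in range(stutter_steps + 1):
            s = allele - k * marker.motif_length
            hh = h * mult * stutter_ratio**k
            add(s, hh * adenylation_split)
            add(s - 1.0, hh * (1.0 - adenylation_split))
    for _ in range(rng.poisson(spurious_rate)):
        add(float(rng.uniform(marker.range_start, marker.range_end)),
            float(rng.uniform(30.0, 300.0)))

    peaks = []
    for size, height in sorted(products.items()):
        scan = int(round(size * 18))
        peaks.append(Peak(
            channel=marker.channel, start_scan=scan - 5, apex_scan=scan,
            end_scan=scan + 5, height=height, area=height * 5,
            size=size + float(rng.normal(0.0, size_jitter)),
        ))
    if rng.random() < saturation_rate and peaks:
        tallest = max(peaks, key=lambda p: p.height)
        tallest.saturated = True
        tallest.saturated_width = int(rng.integers(8, 25))
    if rng.random() < crosstalk_rate:
        size = float(rng.uniform(marker.range_start, marker.range_end))
        scan = int(round(size * 18))
        peaks.append(Peak(
            channel=marker.channel, start_scan=scan - 5, apex_scan=scan,
            end_scan=scan + 5, height=float(rng.uniform(100.0, 5000.0)),
            area=1000.0, size=size, crosstalk=True,
            crosstalk_source=(marker.channel + 1) % 4,
        ))
    return peaks, alleles


def _well_name(i: int) -> str:
    return f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}"


def generate_plate(
    spec: SynthSpec,
    n_samples: int,
    allele_freqs: dict[str, list[tuple[float, float]]] | None = None,
    drift: tuple[float, float] = (0.0, 1.0),
    plate: str = "synthplate",
) -> list[tuple[Chromatogram, TruthRecord]]:
    """Generate a plate of samples with genotypes drawn per marker.

    Alleles are drawn independently (Hardy-Weinberg) from
    ``allele_freqs`` — or uniformly over the motif grid of each marker's
    range when omitted.  ``drift`` applies the same between-run affine
    size perturbation to every sample, exercising the offset
    correction.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(n_samples):
        genotypes = {
            m.name: _draw_genotype(rng, m, (allele_freqs or {}).get(m.name))
            for m in spec.markers
        }
        chrom, truth = generate_chromatogram(
            spec,
            genotypes,
            sample=f"sample{i + 1:03d}",
            drift=drift,
            rng=rng,
            well=_well_name(i),
            plate=plate,
        )
        out.append((chrom, truth))
    return out
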