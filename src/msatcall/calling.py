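"""Allele calling with stutter- and adenylation-aware peak clustering.

Two PCR artifacts multiply the peaks produced by a single allele:

* *stutter* — polymerase slippage yields amplicons differing by whole
  repeat units, a decaying series of peaks spaced by the motif length;
* *adenylation* — non-template addition of one 3' nucleotide; partial
  adenylation splits an allele into two peaks 1 bp apart.

Peaks whose size differences fit either pattern are clustered (by
transitive closure) and the most intense member of each cluster is
taken as the allele.  Peak intensity accounts for camera saturation:
when an apex is clipped, the width of the saturated region stands in
for height.  The number of alleles is capped at the marker's ploidy
(1 or 2); a diploid marker with a single detected allele is reported
homozygous.  Weaker clusters are optionally annotated as *additional
fragments* (possible paralogs, contamination or off-target products)
rather than alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .panels import Bin, Marker, OffsetParams, apply_offset
from .signal import Peak

__all__ = [
    "PeakCluster",
    "Genotype",
    "cluster_peaks",
    "peak_intensity",
    "call_genotype",
    "batch_adenylation_check",
    "manual_edit",
    "DEFAULT_STUTTER_TOL",
    "DEFAULT_ADENYLATION_TOL",
    "DEFAULT_SECONDARY_RATIO",
    "DEFAULT_HET_MIN_RATIO",
]

log = logging.getLogger(__name__)

DEFAULT_STUTTER_TOL = 0.5
DEFAULT_ADENYLATION_TOL = 0.5
DEFAULT_SECONDARY_RATIO = 0.2
DEFAULT_HET_MIN_RATIO = 0.25
#: members of an adenylation pair are "near-equal" when the smaller
#: height is at least this fraction of the larger (batch cross-check)
DEFAULT_ADENYLATION_BALANCE = 0.7
#: sizes within this many bp count as the same allele across a batch
BATCH_SIZE_TOL = 0.35
#: a large additional fragment this far above the called allele triggers
#: a long-allele-dominance warning
LONG_ALLELE_WARN_BP = 60.0


def peak_intensity(peak: Peak) -> tuple[int, float]:
    """Ordering key for peak intensity, saturation-aware.

    Unsaturated peaks compare by apex height.  A saturated peak ranks
    above every unsaturated one — its clipped height underestimates the
    amount of DNA — and saturated peaks compare among themselves by the
    width of the clipped region.
    """
    if peak.saturated:
        return (1, float(peak.saturated_width))
    return (0, float(peak.height))


def _relative_height(p: Peak, q: Peak) -> float:
    """Height of p relative to q for threshold tests.

    Clipped (saturated) heights are used as-is: they are lower bounds,
    which errs toward keeping the weaker peak.
    """
    if q.height <= 0:
        return 1.0
    return p.height / q.height


@dataclass
class PeakCluster:
    """Peaks attributed to one allele (the allele plus its artifacts)."""

    peaks: list[Peak]

    @property
    def principal(self) -> Peak:
        """The member interpreted as the allele: most intense, ties going
        to the longer fragment (full adenylation is the +1 product)."""
        return max(self.peaks, key=lambda p: (peak_intensity(p), p.size))

    @property
    def size(self) -> float:
        return self.principal.size


@dataclass
class Genotype:
    """The call for one sample at one marker."""

    sample: str
    marker: str
    alleles: list[tuple[float, str]] = field(default_factory=list)
    additional_fragments: list[tuple[float, str]] = field(default_factory=list)
    status: str = "called"  # called | manual | no-peak | failed-sizing
    notes: str = ""
    clusters: list[PeakCluster] = field(default_factory=list)


#: a shorter peak can be stutter of a taller one only when its height is
#: below this fraction of the taller peak's; real stutter rarely exceeds
#: ~30% per step, while heterozygote allele peaks are near-balanced
DEFAULT_STUTTER_HEIGHT_MAX = 0.5


def cluster_peaks(
    peaks: list[Peak],
    motif_length: int,
    stutter_tol: float = DEFAULT_STUTTER_TOL,
    adenylation_tol: float = DEFAULT_ADENYLATION_TOL,
    stutter_height_max: float = DEFAULT_STUTTER_HEIGHT_MAX,
) -> list[PeakCluster]:
    """Group in-range peaks into stutter/adenylation clusters.

    Seeded absorption in decreasing intensity order: each unassigned
    peak seeds a cluster (a candidate allele) and absorbs, transitively,
    peaks explainable as its artifacts —

    * stutter: a *shorter* peak whose distance to a member is within
      ``stutter_tol`` of a positive multiple of the motif length and
      whose height is below ``stutter_height_max`` times that member's
      (slippage products decay in height; two alleles of a heterozygote
      also sit whole repeats apart but have comparable heights, and must
      not merge);
    * adenylation: a peak within ``adenylation_tol`` of 1 bp on either
      side of a member, not taller than it (partial adenylation splits
      one allele into near-equal peaks 1 bp apart).

    The 1-bp rule will merge genuinely 1-bp-apart alleles — an error
    mode :func:`batch_adenylation_check` exists to undo.  Clusters are
    disjoint and returned sorted by principal size.
    """
    pk = [p for p in peaks if p.size is not None]
    order = sorted(pk, key=lambda p: (peak_intensity(p), p.size), reverse=True)
    assigned: set[int] = set()
    clusters: list[PeakCluster] = []
    for seed in order:
        if id(seed) in assigned:
            continue
        members = [seed]
        assigned.add(id(seed))
        frontier = [seed]
        while frontier:
            m = frontier.pop()
            for q in pk:
                if id(q) in assigned:
                    continue
                d = q.size - m.size
                join = False
                if abs(abs(d) - 1.0) <= adenylation_tol and q.height <= m.height:
                    join = True
                elif d < 0:
                    steps = round(-d / motif_length)
                    if (
                        steps >= 1
                        and abs(-d - steps * motif_length) <= stutter_tol
                        and q.height <= stutter_height_max * m.height
                    ):
                        join = True
                if join:
                    assigned.add(id(q))
                    members.append(q)
                    frontier.append(q)
        members.sort(key=lambda p: p.size)
        clusters.append(PeakCluster(members))
    clusters.sort(key=lambda c: c.size)
    return clusters


def _name_for(size: float, bins: list[Bin]) -> str:
    for b in bins:
        if b.contains(size):
            return b.name
    return "?"


def call_genotype(
    clusters: list[PeakCluster],
    marker: Marker,
    bins: list[Bin] | None = None,
    additional_detection: bool = True,
    secondary_ratio: float = DEFAULT_SECONDARY_RATIO,
    het_min_ratio: float = DEFAULT_HET_MIN_RATIO,
    sample: str = "",
) -> Genotype:
    """Call alleles from delineated clusters within one marker's range.

    The most intense cluster principal is always an allele — peak
    quality assessment is left to the user.  For diploid markers a
    second cluster becomes the second allele when its principal's
    relative height is at least ``het_min_ratio``; otherwise (and for
    any further clusters) principals at or above ``secondary_ratio``
    times the weakest allele are kept as additional fragments when
    ``additional_detection`` is on.
    """
    if bins is None:
        bins = marker.bins
    gt = Genotype(sample=sample, marker=marker.name)
    if not clusters:
        gt.status = "no-peak"
        return gt
    ranked = sorted(
        clusters, key=lambda c: (peak_intensity(c.principal), c.size), reverse=True
    )
    alleles = [ranked[0]]
    rest = ranked[1:]
    if marker.ploidy == 2 and rest:
        second = rest[0]
        if (
            second.principal.saturated
            or _relative_height(second.principal, ranked[0].principal) >= het_min_ratio
        ):
            alleles.append(second)
            rest = rest[1:]
    gt.alleles = sorted(
        ((c.size, _name_for(c.size, bins)) for c in alleles), key=lambda t: t[0]
    )
    if additional_detection and rest:
        weakest = alleles[-1].principal
        for c in rest:
            if (
                c.principal.saturated
                or _relative_height(c.principal, weakest) >= secondary_ratio
            ):
                gt.additional_fragments.append((c.size, _name_for(c.size, bins)))
        gt.additional_fragments.sort(key=lambda t: t[0])
        top = max(s for s, _ in gt.alleles)
        for s, _ in gt.additional_fragments:
            if s - top > LONG_ALLELE_WARN_BP:
                log.warning(
                    "%s/%s: large fragment %.1f bp sits > %g bp above the called "
                    "allele; possible longer allele suppressed by short-allele dominance",
                    sample, marker.name, s, LONG_ALLELE_WARN_BP,
                )
    gt.clusters = clusters
    gt.status = "called"
    return gt


def exported_alleles(gt: Genotype, ploidy: int) -> list[tuple[float, str]]:
    """Alleles as exported: diploid homozygotes have the allele duplicated."""
    alleles = list(gt.alleles)
    if ploidy == 2 and len(alleles) == 1:
        alleles = alleles * 2
    return alleles


# ---------------------------------------------------------------------------
# batch adenylation cross-check

def _near(a: float, b: float, tol: float = BATCH_SIZE_TOL) -> bool:
    return abs(a - b) <= tol


def _suspect_pairs(gt: Genotype, balance: float) -> list[tuple[Peak, Peak]]:
    """Adenylation merges with near-equal member intensities.

    Returns (shorter, longer) peak pairs ~1 bp apart inside one cluster
    where the smaller height is >= ``balance`` times the larger — the
    situation where the merge may actually hide a 1-bp heterozygote.
    """
    pairs = []
    for cluster in gt.clusters:
        members = sorted(cluster.peaks, key=lambda p: p.size)
        for p, q in zip(members, members[1:]):
            if abs((q.size - p.size) - 1.0) <= DEFAULT_ADENYLATION_TOL:
                hi, lo = max(p.height, q.height), min(p.height, q.height)
                if hi > 0 and lo / hi >= balance:
                    pairs.append((p, q))
    return pairs


def batch_adenylation_check(
    genotypes: list[Genotype],
    marker: Marker,
    balance: float = DEFAULT_ADENYLATION_BALANCE,
    **call_kwargs,
) -> list[Genotype]:
    """Re-examine adenylation merges against other genotypes in the batch.

    The most common calling error is a true 1-bp heterozygote (alleles x
    and x+1) collapsed into one cluster as an adenylation pair.  When
    other genotypes in the same batch carry x and x+1 as *distinct*
    alleles, an x/x+1 merge with near-equal peak heights is unlikely to
    be adenylation: the pair is split into two clusters and the genotype
    re-called.  Returns the revised list; changes are logged.
    """
    if len(genotypes) < 2:
        return genotypes
    out = list(genotypes)
    for idx, gt in enumerate(genotypes):
        if gt.status != "called":
            continue
        for p, q in _suspect_pairs(gt, balance):
            others = [g for g in genotypes if g is not gt and g.status == "called"]
            has_short = any(
                _near(s, p.size) for g in others for s, _ in g.alleles
            )
            has_long = any(
                _near(s, q.size) for g in others for s, _ in g.alleles
            )
            if not (has_short and has_long):
                continue
            # split the containing cluster between p and q
            new_clusters: list[PeakCluster] = []
            for cluster in gt.clusters:
                if p in cluster.peaks and q in cluster.peaks:
                    short_side = [m for m in cluster.peaks
                                  if abs(m.size - p.size) <= abs(m.size - q.size)]
                    long_side = [m for m in cluster.peaks if m not in short_side]
                    new_clusters.append(PeakCluster(short_side))
                    new_clusters.append(PeakCluster(long_side))
                else:
                    new_clusters.append(cluster)
            new_clusters.sort(key=lambda c: c.size)
            revised = call_genotype(
                new_clusters, marker, sample=gt.sample, **call_kwargs
            )
            revised.notes = (gt.notes + " " if gt.notes else "") + \
                "adenylation merge split by batch cross-check"
            log.info(
                "%s/%s: split %.1f/%.1f adenylation merge (batch carries both "
                "as distinct alleles)", gt.sample, marker.name, p.size, q.size,
            )
            out[idx] = revised
            break
    return out


# ---------------------------------------------------------------------------
# manual edits

def manual_edit(
    genotype: Genotype, marker: Marker, action: str, **args
) -> Genotype:
    """Apply a user correction to a genotype; sets status to ``manual``.

    Actions: ``assign-peak-to-bin`` (peak=, bin=), ``move-allele-to-peak``
    (from_size=, peak=), ``toggle-peak`` (peak=), ``rename-allele``
    (size=, name=).  The ploidy cap is preserved: assigning a peak to a
    full diploid genotype replaces the nearer-sized allele.
    """

    def check_range(size: float) -> None:
        if not marker.range_start <= size <= marker.range_end:
            raise ValueError(
                f"peak at {size:.2f} bp outside range of marker '{marker.name}'"
            )

    if action == "assign-peak-to-bin":
        peak: Peak = args["peak"]
        target: Bin = args["bin"]
        check_range(peak.size)
        _upsert_allele(genotype, marker, peak.size, target.name)
    elif action == "move-allele-to-peak":
        from_size: float = args["from_size"]
        peak = args["peak"]
        check_range(peak.size)
        genotype.alleles = [a for a in genotype.alleles if a[0] != from_size]
        name = _name_for(peak.size, marker.bins)
        genotype.alleles.append((peak.size, name))
        genotype.alleles.sort(key=lambda t: t[0])
    elif action == "toggle-peak":
        peak = args["peak"]
        check_range(peak.size)
        existing = [a for a in genotype.alleles if a[0] == peak.size]
        if existing:
            genotype.alleles = [a for a in genotype.alleles if a[0] != peak.size]
        else:
            _upsert_allele(genotype, marker, peak.size,
                           _name_for(peak.size, marker.bins))
    elif action == "rename-allele":
        size, name = args["size"], args["name"]
        genotype.alleles = [
            (s, name if s == size else n) for s, n in genotype.alleles
        ]
    else:
        raise ValueError(f"unknown edit action: {action}")
    genotype.status = "manual"
    return genotype


def _upsert_allele(gt: Genotype, marker: Marker, size: float, name: str) -> None:
    for i, (s, _) in enumerate(gt.alleles):
        if s == size:
            gt.alleles[i] = (size, name)
            return
    if len(gt.alleles) >= marker.ploidy:
        nearest = min(range(len(gt.alleles)),
                      key=lambda i: abs(gt.alleles[i][0] - size))
        del gt.alleles[nearest]
    gt.alleles.append((size, name))
    gt.alleles.sort(key=lambda t: t[0])


def size_peaks(
    peaks: list[Peak], fit, offset: OffsetParams | None = None
) -> list[Peak]:
    """Annotate peaks with offset-corrected sizes from a sizing fit."""
    from .sizing import size_at_scan

    for p in peaks:
        raw = size_at_scan(fit, p.apex_scan)
        p.size = apply_offset(raw, offset) if offset is not None else raw
    return peaks
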