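"""Marker panels, allele bins, and the inter-run size-offset correction.

A *marker* is one microsatellite locus: a dye channel, a ploidy (1 or
2), the repeat-motif length and the bp range its alleles occupy.
Markers amplified together in one multiplex PCR form a *panel*.  *Bins*
are disjoint bp intervals inside a marker's range naming the expected
allele sizes.

Fragment sizes estimated from the DNA ladder drift slightly between
sequencer runs.  Rather than moving bins per run, the estimated sizes
are corrected with an affine map y = a + b*x.  The offset parameters
(a, b) follow from moving the bin-set range as a whole: if the range
[s, e] is moved to [s', e'] so that bins coincide with peaks, then

    b = (e' - s') / (e - s)        a = s' - s * b

which maps s -> s' and e -> e' exactly.  No correction is (a=0, b=1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Marker",
    "Bin",
    "OffsetParams",
    "Panel",
    "make_bin_set",
    "offset_from_move",
    "apply_offset",
    "read_panel",
    "write_panel",
]

log = logging.getLogger(__name__)


@dataclass
class Bin:
    """A named bp interval marking an expected allele size."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"bin '{self.name}': start must be < end")

    def contains(self, size: float) -> bool:
        return self.start <= size <= self.end


@dataclass
class Marker:
    """A microsatellite locus with its dye, ploidy, motif and size range."""

    name: str
    channel: int
    ploidy: int
    motif_length: int
    range_start: float
    range_end: float
    bins: list[Bin] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"marker '{self.name}': ploidy must be 1 or 2")
        if self.motif_length < 1:
            raise ValueError(f"marker '{self.name}': motif_length must be >= 1")
        if not self.range_start < self.range_end:
            raise ValueError(f"marker '{self.name}': range_start must be < range_end")
        self.validate_bins()

    def validate_bins(self) -> None:
        # a bin's centre must lie in the marker range; edge bins may
        # overhang by up to half their width (a 1-bp bin centred exactly
        # on the range boundary is legitimate)
        ordered = sorted(self.bins, key=lambda b: b.start)
        for b in ordered:
            centre = (b.start + b.end) / 2.0
            if centre < self.range_start or centre > self.range_end:
                raise ValueError(
                    f"marker '{self.name}': bin '{b.name}' outside marker range"
                )
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"marker '{self.name}': bins '{a.name}' and '{b.name}' overlap"
                )

    def bin_for(self, size: float) -> Bin | None:
        for b in self.bins:
            if b.contains(size):
                return b
        return None


@dataclass
class Panel:
    """A named multiplex: the markers scored together in one PCR."""

    name: str
    markers: list[Marker] = field(default_factory=list)

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"no marker '{name}' in panel '{self.name}'")


@dataclass(frozen=True)
class OffsetParams:
    """Affine size correction y = a + b*x for one (sample set, marker)."""

    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("offset slope b must be positive")


IDENTITY_OFFSET = OffsetParams(0.0, 1.0)


def make_bin_set(
    marker: Marker, width: float, spacing: float, anchor: float
) -> list[Bin]:
    """Generate automatically named bins across a marker's range.

    Bins of the given ``width`` are centred at ``anchor + k*spacing``
    for every integer k that keeps the centre inside the marker range;
    each is named after its centre rounded to the nearest integer (ties
    round half-up).  ``spacing`` is typically the repeat motif length.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if width > spacing:
        raise ValueError("overlapping bins: width must not exceed spacing")
    if not marker.range_start <= anchor <= marker.range_end:
        raise ValueError("anchor outside marker range")
    half = width / 2.0
    k_min = math.ceil((marker.range_start - anchor) / spacing - 1e-9)
    k_max = math.floor((marker.range_end - anchor) / spacing + 1e-9)
    bins = []
    for k in range(k_min, k_max + 1):
        center = anchor + k * spacing
        name = str(int(math.floor(center + 0.5)))
        bins.append(Bin(name, center - half, center + half))
    return bins


def offset_from_move(s: float, e: float, s_new: float, e_new: float) -> OffsetParams:
    """Offset parameters from moving the bin-set range [s, e] to [s', e'].

    Solves {s' = a + b*s, e' = a + b*e}: b = (e'-s')/(e-s), a = s' - s*b.
    The returned map sends s to s' and e to e' exactly.
    """
    if e <= s:
        raise ValueError("degenerate bin-set range: e must exceed s")
    if e_new <= s_new:
        raise ValueError("degenerate moved range: e' must exceed s'")
    b = (e_new - s_new) / (e - s)
    a = s_new - s * b
    return OffsetParams(a, b)


def apply_offset(size: float, offset: OffsetParams) -> float:
    """Corrected fragment size y = a + b*x."""
    return offset.a + offset.b * size


# ---------------------------------------------------------------------------
# panel text format
#
# UTF-8 TSV, one row per object:
#   panel<TAB>name
#   marker<TAB>name<TAB>channel<TAB>ploidy<TAB>motif<TAB>start<TAB>end
#   bin<TAB>name<TAB>start<TAB>end        (belongs to the preceding marker)
#
# A best-effort importer also accepts the tab-delimited GeneMapper panel
# layout (Panel/Marker rows), mapping unsupported fields to defaults.


class PanelFormatError(ValueError):
    pass


def read_panel(path: str | Path) -> Panel:
    """Read a panel from the native TSV dialect or a GeneMapper export."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln.rstrip("\n").split("\t") for ln in lines if ln.strip()]
    if not rows:
        log.warning("panel file %s is empty", path)
        return Panel(name=Path(path).stem)
    kinds = {r[0].strip().lower() for r in rows}
    if kinds <= {"panel", "marker", "bin"}:  # native dialect: keyword rows only
        return _read_native(rows, path)
    return _read_genemapper(rows, path)


def _num(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PanelFormatError(f"line {lineno}: bad {what}: {text!r}") from None


def _read_native(rows: list[list[str]], path) -> Panel:
    panel = Panel(name=Path(path).stem)
    current: Marker | None = None
    for lineno, row in enumerate(rows, start=1):
        kind = row[0].strip().lower()
        try:
            if kind == "panel":
                panel.name = row[1]
            elif kind == "marker":
                if len(row) < 7:
                    raise PanelFormatError(f"line {lineno}: marker row needs 7 fields")
                current = Marker(
                    name=row[1],
                    channel=int(_num(row[2], lineno, "channel")),
                    ploidy=int(_num(row[3], lineno, "ploidy")),
                    motif_length=int(_num(row[4], lineno, "motif")),
                    range_start=_num(row[5], lineno, "start"),
                    range_end=_num(row[6], lineno, "end"),
                )
                panel.markers.append(current)
            elif kind == "bin":
                if current is None:
                    raise PanelFormatError(f"line {lineno}: bin row before any marker")
                if len(row) < 4:
                    raise PanelFormatError(f"line {lineno}: bin row needs 4 fields")
                current.bins.append(
                    Bin(row[1], _num(row[2], lineno, "start"), _num(row[3], lineno, "end"))
                )
                current.validate_bins()
            else:
                raise PanelFormatError(f"line {lineno}: unknown row kind {row[0]!r}")
        except ValueError as exc:
            if isinstance(exc, PanelFormatError):
                raise
            raise PanelFormatError(f"line {lineno}: {exc}") from exc
    return panel


_GM_DYE_INDEX = {"B": 0, "G": 1, "Y": 2, "R": 3, "O": 4}


def _read_genemapper(rows: list[list[str]], path) -> Panel:
    """Best-effort import of a GeneMapper panel export.

    Recognised layouts: ``Panel<TAB>name...`` header rows and marker rows
    ``name<TAB>dye<TAB>min<TAB>max<TAB>...``; everything GeneMapper
    encodes beyond name/dye/range is mapped to defaults with a warning.
    """
    panel = Panel(name=Path(path).stem)
    for lineno, row in enumerate(rows, start=1):
        head = row[0].strip()
        if head.lower().startswith(("version", "chemistry", "kit")):
            continue
        if head.lower() == "panel" and len(row) > 1:
            panel.name = row[1]
            continue
        if len(row) >= 4:
            dye = row[1].strip().upper()[:1]
            channel = _GM_DYE_INDEX.get(dye)
            if channel is None:
                log.warning("line %d: unknown dye %r, defaulting to channel 0",
                            lineno, row[1])
                channel = 0
            try:
                start = float(row[2])
                end = float(row[3])
            except ValueError:
                continue  # metadata row
            log.warning(
                "line %d: GeneMapper row lacks ploidy/motif; defaulting to diploid dinucleotide",
                lineno,
            )
            panel.markers.append(
                Marker(
                    name=head,
                    channel=channel,
                    ploidy=2,
                    motif_length=2,
                    range_start=start,
                    range_end=end,
                )
            )
    return panel


def write_panel(panel: Panel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"panel\t{panel.name}\n")
        for m in panel.markers:
            fh.write(
                f"marker\t{m.name}\t{m.channel}\t{m.ploidy}\t{m.motif_length}"
                f"\t{m.range_start!r}\t{m.range_end!r}\n"
            )
            for b in m.bins:
                # repr round-trips floats exactly
                fh.write(f"bin\t{b.name}\t{b.start!r}\t{b.end!r}\n")
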