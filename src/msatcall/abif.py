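"""Reading and writing chromatograms in the ABIF binary container (.fsa).

ABIF is the big-endian tagged container produced by Applied Biosystems
capillary sequencers.  A file starts with the 4-byte magic ``ABIF``, a
version number, and a root directory entry pointing at a table of 28-byte
directory entries; each entry names a (tag, number) pair and locates its
payload.  Only the tags needed for fragment analysis are interpreted here:

========  ======================================================
``DATA``  raw fluorescence traces (numbers 1-4, plus 105 for a
          fifth dye)
``DyeN``  dye name per channel
``SMPL``  sample name
``TUBE``  plate well (e.g. ``A01``)
``CTNM``  container (plate) name
``RUND``  run date
``Satd``  saturated scan indices per channel, when recorded by
          the instrument
========  ======================================================

The writer emits a minimal, spec-conformant file that the reader parses
back bit-identically, which makes the whole pipeline testable from
synthetic data alone.
"""

from __future__ import annotations

import datetime
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Chromatogram", "AbifError", "read_fsa", "write_fsa"]

_MAGIC = b"ABIF"
_VERSION = 101
_DIR_STRUCT = struct.Struct(">4sihhiiii")  # name, number, etype, esize, nelem, dsize, doffset, dhandle
_HEADER_SIZE = 128

# ABIF element type codes
_T_BYTE = 1
_T_SHORT = 4
_T_LONG = 5
_T_DATE = 10
_T_PSTRING = 18
_T_CSTRING = 19

SHORT_MIN = -32768
SHORT_MAX = 32767

#: fluorescence level above which a flat-topped plateau is treated as
#: camera saturation (see :func:`_detect_saturation`)
SATURATION_FLOOR = 30000
_PLATEAU_MIN_RUN = 3


class AbifError(ValueError):
    """Raised for files that are not valid, complete ABIF containers."""


@dataclass
class Chromatogram:
    """A multi-channel capillary electrophoresis trace plus run metadata.

    ``channels`` holds one integer fluorescence sequence per dye, all of
    equal length ``scan_count``.  ``saturation_regions`` are half-open
    ``(channel, start_scan, end_scan)`` intervals where the sequencer
    camera clipped the signal, so peak height there underestimates the
    amount of DNA.
    """

    sample_name: str = ""
    plate_name: str = ""
    well: str = ""
    run_date: datetime.date | None = None
    dye_names: list[str] = field(default_factory=list)
    channels: list[np.ndarray] = field(default_factory=list)
    saturation_regions: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def scan_count(self) -> int:
        return len(self.channels[0]) if self.channels else 0

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def validate(self) -> None:
        if not 4 <= len(self.channels) <= 5:
            raise ValueError(
                f"unsupported channel count: {len(self.channels)} (need 4 or 5)"
            )
        n = self.scan_count
        if n == 0:
            raise ValueError("empty trace")
        for i, ch in enumerate(self.channels):
            if len(ch) != n:
                raise ValueError(f"channel {i} length {len(ch)} != scan count {n}")
            arr = np.asarray(ch)
            if arr.min(initial=0) < SHORT_MIN:
                raise ValueError(f"channel {i} below signed-16-bit floor")
        for c, s, e in self.saturation_regions:
            if not (0 <= c < len(self.channels) and 0 <= s < e <= n):
                raise ValueError(f"saturation region ({c},{s},{e}) out of bounds")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return (
            self.sample_name == other.sample_name
            and self.plate_name == other.plate_name
            and self.well == other.well
            and self.run_date == other.run_date
            and self.dye_names == other.dye_names
            and len(self.channels) == len(other.channels)
            and all(
                np.array_equal(a, b) for a, b in zip(self.channels, other.channels)
            )
            and sorted(self.saturation_regions) == sorted(other.saturation_regions)
        )


def _detect_saturation(channels: list[np.ndarray]) -> list[tuple[int, int, int]]:
    """Find flat-topped plateaus where the camera clipped the signal.

    A run of >= 3 consecutive scans within 1 fluorescence unit of the
    channel's global maximum counts as saturated, provided that maximum
    is at least :data:`SATURATION_FLOOR` — genuine peaks are never that
    flat at their apex.
    """
    regions: list[tuple[int, int, int]] = []
    for c, trace in enumerate(channels):
        arr = np.asarray(trace)
        if arr.size == 0:
            continue
        peak = int(arr.max())
        if peak < SATURATION_FLOOR:
            continue
        at_top = arr >= peak - 1
        # maximal runs of True
        padded = np.concatenate(([False], at_top, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            if e - s >= _PLATEAU_MIN_RUN:
                regions.append((c, int(s), int(e)))
    return regions


# ---------------------------------------------------------------------------
# reading

def _read_exact(buf: bytes, offset: int, size: int) -> bytes:
    if offset < 0 or offset + size > len(buf):
        raise AbifError("corrupt file: record extends past end of file")
    return buf[offset : offset + size]


def _entry_payload(buf: bytes, entry: tuple) -> bytes:
    _, _, _, _, _, dsize, doffset, _ = entry
    if dsize <= 4:
        return struct.pack(">i", doffset)[:dsize]
    return _read_exact(buf, doffset, dsize)


def _decode_string(etype: int, payload: bytes) -> str:
    if etype == _T_PSTRING:
        if not payload:
            return ""
        n = payload[0]
        return payload[1 : 1 + n].decode("latin-1")
    if etype == _T_CSTRING:
        return payload.rstrip(b"\x00").decode("latin-1")
    return payload.decode("latin-1", errors="replace")


def read_fsa(path: str | Path) -> Chromatogram:
    """Parse an ABIF ``.fsa`` file into a :class:`Chromatogram`.

    Raw data channels are taken from tags ``DATA`` 1-4 (plus ``DATA``
    105 when a fifth dye is present).  Missing metadata tags yield empty
    strings.  Saturation regions come from ``Satd`` tags when present,
    otherwise from flat-top plateau detection.

    Raises :class:`AbifError` for non-ABIF files, files with fewer than
    4 data channels, or truncated directories.
    """
    buf = Path(path).read_bytes()
    if buf[:4] != _MAGIC:
        raise AbifError(f"not an ABIF file: {path}")
    if len(buf) < 6 + _DIR_STRUCT.size:
        raise AbifError("corrupt file: header truncated")
    root = _DIR_STRUCT.unpack_from(buf, 6)
    _, _, _, _, nelem, dsize, doffset, _ = root
    if dsize != nelem * _DIR_STRUCT.size:
        raise AbifError("corrupt file: directory size mismatch")
    if doffset + dsize > len(buf):
        raise AbifError("corrupt file: directory truncated")

    entries: dict[tuple[str, int], tuple] = {}
    for i in range(nelem):
        entry = _DIR_STRUCT.unpack_from(buf, doffset + i * _DIR_STRUCT.size)
        name = entry[0].decode("latin-1")
        entries[(name, entry[1])] = entry

    def get_string(tag: str, number: int) -> str:
        entry = entries.get((tag, number))
        if entry is None:
            return ""
        return _decode_string(entry[2], _entry_payload(buf, entry))

    # channels: DATA 1..4 (+105)
    channels: list[np.ndarray] = []
    for number in (1, 2, 3, 4, 105):
        entry = entries.get(("DATA", number))
        if entry is None:
            continue
        payload = _entry_payload(buf, entry)
        etype = entry[2]
        if etype == _T_SHORT:
            arr = np.frombuffer(payload, dtype=">i2").astype(np.int64)
        elif etype == _T_LONG:
            arr = np.frombuffer(payload, dtype=">i4").astype(np.int64)
        else:
            raise AbifError(f"unsupported DATA element type {etype}")
        channels.append(arr)
    if len(channels) < 4:
        raise AbifError(
            f"unsupported channel count: found {len(channels)} DATA channels, need >= 4"
        )

    dye_names = []
    for i in range(1, len(channels) + 1):
        dye_names.append(get_string("DyeN", i))

    run_date = None
    rund = entries.get(("RUND", 1))
    if rund is not None:
        payload = _entry_payload(buf, rund)
        if len(payload) >= 4:
            year, month, day = struct.unpack(">hBB", payload[:4])
            try:
                run_date = datetime.date(year, month, day)
            except ValueError:
                run_date = None

    # saturation: Satd tags (one per channel, listing scan indices) win
    # over plateau detection
    regions: list[tuple[int, int, int]] = []
    have_satd = False
    for c in range(len(channels)):
        entry = entries.get(("Satd", c + 1))
        if entry is None:
            continue
        have_satd = True
        payload = _entry_payload(buf, entry)
        scans = np.frombuffer(payload, dtype=">i4")
        if scans.size:
            breaks = np.flatnonzero(np.diff(scans) != 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [scans.size - 1]))
            for s, e in zip(starts, ends):
                regions.append((c, int(scans[s]), int(scans[e]) + 1))
    if not have_satd:
        regions = _detect_saturation(channels)

    return Chromatogram(
        sample_name=get_string("SMPL", 1),
        plate_name=get_string("CTNM", 1),
        well=get_string("TUBE", 1),
        run_date=run_date,
        dye_names=dye_names,
        channels=channels,
        saturation_regions=regions,
    )


# ---------------------------------------------------------------------------
# writing

def _pstring(text: str) -> bytes:
    raw = text.encode("latin-1")[:255]
    return bytes([len(raw)]) + raw


def write_fsa(chromatogram: Chromatogram, path: str | Path) -> None:
    """Write a minimal valid ABIF file that :func:`read_fsa` round-trips.

    Refuses chromatograms violating the container's constraints (channel
    count outside 4-5, empty traces, sub-int16 fluorescence).
    """
    chromatogram.validate()
    records: list[tuple[str, int, int, int, int, bytes]] = []

    def add(tag: str, number: int, etype: int, esize: int, nelem: int, payload: bytes):
        records.append((tag, number, etype, esize, nelem, payload))

    data_numbers = [1, 2, 3, 4] + ([105] if chromatogram.n_channels == 5 else [])
    for number, trace in zip(data_numbers, chromatogram.channels):
        arr = np.asarray(trace)
        if arr.size and arr.max() <= SHORT_MAX and arr.min() >= SHORT_MIN:
            add("DATA", number, _T_SHORT, 2, arr.size,
                arr.astype(">i2").tobytes())
        else:
            add("DATA", number, _T_LONG, 4, arr.size,
                arr.astype(">i4").tobytes())

    dyes = list(chromatogram.dye_names) or [
        f"DYE{i + 1}" for i in range(chromatogram.n_channels)
    ]
    for i, dye in enumerate(dyes[: chromatogram.n_channels], start=1):
        p = _pstring(dye)
        add("DyeN", i, _T_PSTRING, 1, len(p), p)

    if chromatogram.sample_name:
        p = _pstring(chromatogram.sample_name)
        add("SMPL", 1, _T_PSTRING, 1, len(p), p)
    if chromatogram.well:
        p = _pstring(chromatogram.well)
        add("TUBE", 1, _T_PSTRING, 1, len(p), p)
    if chromatogram.plate_name:
        p = chromatogram.plate_name.encode("latin-1") + b"\x00"
        add("CTNM", 1, _T_CSTRING, 1, len(p), p)
    if chromatogram.run_date is not None:
        d = chromatogram.run_date
        add("RUND", 1, _T_DATE, 4, 1, struct.pack(">hBB", d.year, d.month, d.day))

    per_channel_sat: dict[int, list[int]] = {}
    for c, s, e in chromatogram.saturation_regions:
        per_channel_sat.setdefault(c, []).extend(range(s, e))
    for c, scans in sorted(per_channel_sat.items()):
        arr = np.array(sorted(set(scans)), dtype=">i4")
        add("Satd", c + 1, _T_LONG, 4, arr.size, arr.tobytes())

    # layout: 128-byte header, payloads, directory table at the end
    offset = _HEADER_SIZE
    dir_entries = []
    payload_blobs = []
    for tag, number, etype, esize, nelem, payload in records:
        dsize = len(payload)
        if dsize <= 4:
            doffset = int.from_bytes(payload.ljust(4, b"\x00"), "big", signed=True)
        else:
            doffset = offset
            payload_blobs.append(payload)
            offset += dsize
        dir_entries.append(
            _DIR_STRUCT.pack(tag.encode("latin-1"), number, etype, esize,
                             nelem, dsize, doffset, 0)
        )

    dir_offset = offset
    root = _DIR_STRUCT.pack(
        b"tdir", 1, 1023, _DIR_STRUCT.size, len(dir_entries),
        len(dir_entries) * _DIR_STRUCT.size, dir_offset, 0
    )
    header = _MAGIC + struct.pack(">h", _VERSION) + root
    header = header.ljust(_HEADER_SIZE, b"\x00")

    with open(path, "wb") as fh:
        fh.write(header)
        for blob in payload_blobs:
            fh.write(blob)
        for entry in dir_entries:
            fh.write(entry)
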