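"""Project management: samples, folders, panels, standards, fits,
offsets and genotypes, with JSON persistence and tabular export.

The on-disk format is a documented JSON file referencing (or optionally
embedding) the FSA chromatograms, so projects are portable and
diff-able.  Saved filter criteria act like smart folders: they are
re-evaluated on every call, so results update as the project changes.
"""

from __future__ import annotations

import base64
import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calling, signal, sizing
from .abif import Chromatogram, read_fsa, write_fsa
from .calling import Genotype, exported_alleles
from .panels import Bin, Marker, OffsetParams, Panel
from .signal import Peak
from .sizing import SizeStandard, SizingFit

__all__ = [
    "Project",
    "Sample",
    "Folder",
    "import_samples",
    "apply_standard",
    "apply_panel",
    "call_genotypes",
    "filter_samples",
    "filter_genotypes",
    "export_genotypes",
    "save_project",
    "load_project",
]

log = logging.getLogger(__name__)

FORMAT_NAME = "msatcall-project"
FORMAT_VERSION = 1


def normalize_well(well: str) -> str:
    """Normalize well ids to letter + 2-digit form ('a1' -> 'A01')."""
    m = re.fullmatch(r"([A-Za-z])\s*0*(\d{1,2})", well.strip())
    if not m:
        return well
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


@dataclass
class Sample:
    name: str
    path: str = ""
    plate: str = ""
    well: str = ""
    run_date: datetime.date | None = None
    fit: SizingFit | None = None
    quality: float | None = None
    offsets: dict[str, OffsetParams] = field(default_factory=dict)
    panel: str | None = None
    chromatogram: Chromatogram | None = None

    def load_chromatogram(self) -> Chromatogram:
        if self.chromatogram is None:
            self.chromatogram = read_fsa(self.path)
        return self.chromatogram


@dataclass
class Folder:
    name: str
    samples: list[str] = field(default_factory=list)
    subfolders: list["Folder"] = field(default_factory=list)

    def folder(self, name: str) -> "Folder":
        if name == self.name:
            return self
        for sub in self.subfolders:
            try:
                return sub.folder(name)
            except KeyError:
                pass
        raise KeyError(f"no folder '{name}'")

    def all_samples(self) -> list[str]:
        out = list(self.samples)
        for sub in self.subfolders:
            out.extend(sub.all_samples())
        return out


@dataclass
class Project:
    root: Folder = field(default_factory=lambda: Folder("root"))
    samples: dict[str, Sample] = field(default_factory=dict)
    panels: dict[str, Panel] = field(default_factory=dict)
    standards: dict[str, SizeStandard] = field(default_factory=dict)
    genotypes: dict[tuple[str, str], Genotype] = field(default_factory=dict)

    def folder_samples(self, folder: str | None) -> list[Sample]:
        names = (
            self.root.all_samples()
            if folder is None
            else self.root.folder(folder).all_samples()
        )
        return [self.samples[n] for n in names]


# ---------------------------------------------------------------------------
# batch operations

@dataclass
class ImportReport:
    succeeded: list[str] = field(default_factory=list)
    failed: list[tuple[str, str]] = field(default_factory=list)  # (path, error)


def import_samples(
    project: Project, paths: list[str | Path], folder: str | None = None
) -> ImportReport:
    """Parse each FSA file into the project; per-file errors never abort
    the batch."""
    dest = project.root if folder is None else project.root.folder(folder)
    report = ImportReport()
    for path in paths:
        try:
            chrom = read_fsa(path)
        except (OSError, ValueError) as exc:
            report.failed.append((str(path), str(exc)))
            continue
        name = chrom.sample_name or Path(path).stem
        base, k = name, 1
        while name in project.samples:
            k += 1
            name = f"{base}-{k}"
        project.samples[name] = Sample(
            name=name,
            path=str(path),
            plate=chrom.plate_name,
            well=normalize_well(chrom.well),
            run_date=chrom.run_date,
            chromatogram=chrom,
        )
        dest.samples.append(name)
        report.succeeded.append(name)
    return report


def apply_standard(
    project: Project,
    standard: SizeStandard,
    degree: int = 3,
    folder: str | None = None,
    samples: list[str] | None = None,
    ladder_channel: int | None = None,
) -> dict[str, SizingFit | str]:
    """Assign ladder fragments and fit the sizing for each sample.

    Returns per-sample fits, or the error message where sizing failed.
    The ladder channel defaults to the last channel (where the
    size-standard dye conventionally sits).
    """
    project.standards.setdefault(standard.name, standard)
    targets = (
        [project.samples[s] for s in samples]
        if samples is not None
        else project.folder_samples(folder)
    )
    results: dict[str, SizingFit | str] = {}
    for sample in targets:
        try:
            chrom = sample.load_chromatogram()
            ch = ladder_channel if ladder_channel is not None else chrom.n_channels - 1
            per_channel = signal.detect_all_channels(chrom)
            fit = sizing.size_ladder(per_channel[ch], standard, degree=degree)
            sample.fit = fit
            sample.quality = fit.quality
            results[sample.name] = fit
        except (ValueError, OSError) as exc:
            sample.fit = None
            sample.quality = 0.0
            results[sample.name] = str(exc)
    return results


def apply_panel(
    project: Project,
    panel: Panel,
    folder: str | None = None,
    samples: list[str] | None = None,
) -> list[Genotype]:
    """Associate a marker panel: one empty genotype per sample x marker."""
    project.panels.setdefault(panel.name, panel)
    targets = (
        [project.samples[s] for s in samples]
        if samples is not None
        else project.folder_samples(folder)
    )
    created = []
    for sample in targets:
        sample.panel = panel.name
        for marker in panel.markers:
            gt = Genotype(sample=sample.name, marker=marker.name, status="no-peak")
            project.genotypes[(sample.name, marker.name)] = gt
            created.append(gt)
    return created


def _marker_peaks(
    sample: Sample, marker: Marker, offset: OffsetParams | None
) -> list[Peak]:
    chrom = sample.load_chromatogram()
    per_channel = signal.detect_all_channels(chrom)
    peaks = [p for p in per_channel[marker.channel] if not p.crosstalk]
    calling.size_peaks(peaks, sample.fit, offset)
    return [
        p for p in peaks if marker.range_start <= p.size <= marker.range_end
    ]


def call_genotypes(
    project: Project,
    folder: str | None = None,
    samples: list[str] | None = None,
    additional_detection: bool = True,
    adenylation_cross_check: bool = True,
    **call_kwargs,
) -> list[Genotype]:
    """Run the allele caller for every sample x marker in scope."""
    targets = (
        [project.samples[s] for s in samples]
        if samples is not None
        else project.folder_samples(folder)
    )
    stutter_tol = call_kwargs.pop("stutter_tol", calling.DEFAULT_STUTTER_TOL)
    adenylation_tol = call_kwargs.pop("adenylation_tol",
                                      calling.DEFAULT_ADENYLATION_TOL)
    called: list[Genotype] = []
    by_marker: dict[str, list[Genotype]] = {}
    for sample in targets:
        if sample.panel is None:
            continue
        panel = project.panels[sample.panel]
        for marker in panel.markers:
            key = (sample.name, marker.name)
            if sample.fit is None:
                gt = Genotype(sample=sample.name, marker=marker.name,
                              status="failed-sizing")
            else:
                offset = sample.offsets.get(marker.name)
                peaks = _marker_peaks(sample, marker, offset)
                clusters = calling.cluster_peaks(
                    peaks, marker.motif_length,
                    stutter_tol=stutter_tol,
                    adenylation_tol=adenylation_tol,
                )
                gt = calling.call_genotype(
                    clusters, marker,
                    additional_detection=additional_detection,
                    sample=sample.name, **call_kwargs,
                )
            project.genotypes[key] = gt
            called.append(gt)
            by_marker.setdefault(marker.name, []).append(gt)
    if adenylation_cross_check:
        markers = {
            m.name: m for p in project.panels.values() for m in p.markers
        }
        for mname, gts in by_marker.items():
            revised = calling.batch_adenylation_check(gts, markers[mname])
            for gt in revised:
                project.genotypes[(gt.sample, gt.marker)] = gt
    return [project.genotypes[(g.sample, g.marker)] for g in called]


# ---------------------------------------------------------------------------
# filtering (smart-folder style: criteria re-evaluated on each call)

_SAMPLE_FIELDS = {
    "name": lambda s: s.name,
    "plate": lambda s: s.plate,
    "well": lambda s: s.well,
    "run_date": lambda s: s.run_date,
    "quality": lambda s: s.quality,
    "panel": lambda s: s.panel,
}

_GENOTYPE_FIELDS = {
    "sample": lambda g: g.sample,
    "marker": lambda g: g.marker,
    "status": lambda g: g.status,
    "allele_name": lambda g: [n for _, n in g.alleles],
    "allele_size": lambda g: [s for s, _ in g.alleles],
    "notes": lambda g: g.notes,
}

_OPS = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a is not None and a < b,
    "<=": lambda a, b: a is not None and a <= b,
    ">": lambda a, b: a is not None and a > b,
    ">=": lambda a, b: a is not None and a >= b,
    "contains": lambda a, b: b in (a or ""),
}


def _match(item, criteria, fields, combine: str) -> bool:
    if not criteria:
        return True
    results = []
    for fname, op, value in criteria:
        if fname not in fields:
            raise ValueError(
                f"unknown field '{fname}'; valid fields: {sorted(fields)}"
            )
        if op not in _OPS:
            raise ValueError(f"unknown operator '{op}'; valid: {sorted(_OPS)}")
        actual = fields[fname](item)
        if isinstance(actual, datetime.date) and isinstance(value, str):
            value = datetime.date.fromisoformat(value)
        if isinstance(actual, list):
            results.append(any(_OPS[op](a, value) for a in actual))
        else:
            results.append(_OPS[op](actual, value))
    return all(results) if combine == "and" else any(results)


def filter_samples(project: Project, criteria, combine: str = "and") -> list[Sample]:
    """Samples matching (field, op, value) criteria joined by and/or."""
    return [
        s for s in project.samples.values()
        if _match(s, criteria, _SAMPLE_FIELDS, combine)
    ]


def filter_genotypes(project: Project, criteria, combine: str = "and") -> list[Genotype]:
    return [
        g for g in project.genotypes.values()
        if _match(g, criteria, _GENOTYPE_FIELDS, combine)
    ]


# ---------------------------------------------------------------------------
# export

_EXPORT_COLUMNS = [
    "sample", "plate", "well", "run_date", "marker",
    "allele1", "allele2", "size1", "size2",
    "additional_fragments", "status", "notes",
]


def export_genotypes(
    project: Project, selection: list[Genotype], path: str | Path
) -> None:
    """Write genotypes + sample metadata as UTF-8 TSV, one row each.

    Homozygous diploid calls duplicate the allele in both columns;
    sizes are offset-applied, 2-decimal bp; additional fragments are
    listed in their own column, never among the alleles.
    """
    if not selection:
        raise ValueError("empty genotype selection")
    markers = {m.name: m for p in project.panels.values() for m in p.markers}
    rows = []
    for gt in sorted(selection, key=lambda g: (g.sample, g.marker)):
        sample = project.samples.get(gt.sample)
        ploidy = markers[gt.marker].ploidy if gt.marker in markers else 2
        alleles = exported_alleles(gt, ploidy)
        names = [n for _, n in alleles] + ["", ""]
        sizes = [f"{s:.2f}" for s, _ in alleles] + ["", ""]
        extra = ";".join(f"{s:.2f}:{n}" for s, n in gt.additional_fragments)
        rows.append([
            gt.sample,
            sample.plate if sample else "",
            sample.well if sample else "",
            sample.run_date.isoformat() if sample and sample.run_date else "",
            gt.marker,
            names[0], names[1], sizes[0], sizes[1],
            extra, gt.status, gt.notes,
        ])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EXPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# persistence

def _fit_to_json(fit: SizingFit) -> dict:
    return {
        "degree": fit.degree,
        "coefficients": list(map(float, fit.coefficients)),
        "quality": fit.quality,
        "assignments": [
            {"peak": _peak_to_json(p), "size": s} for p, s in fit.assignments
        ],
        "residuals": list(map(float, fit.residuals)),
    }


def _fit_from_json(d: dict) -> SizingFit:
    return SizingFit(
        degree=d["degree"],
        coefficients=np.asarray(d["coefficients"]),
        assignments=[(_peak_from_json(a["peak"]), a["size"])
                     for a in d["assignments"]],
        residuals=np.asarray(d["residuals"]),
        quality=d["quality"],
    )


_PEAK_KEYS = (
    "channel", "start_scan", "apex_scan", "end_scan", "height", "area",
    "saturated", "saturated_width", "crosstalk", "crosstalk_source", "size",
)


def _peak_to_json(p: Peak) -> dict:
    return {k: getattr(p, k) for k in _PEAK_KEYS}


def _peak_from_json(d: dict) -> Peak:
    return Peak(**{k: d[k] for k in _PEAK_KEYS})


def _genotype_to_json(g: Genotype) -> dict:
    return {
        "sample": g.sample,
        "marker": g.marker,
        "alleles": [[s, n] for s, n in g.alleles],
        "additional_fragments": [[s, n] for s, n in g.additional_fragments],
        "status": g.status,
        "notes": g.notes,
    }


def _genotype_from_json(d: dict) -> Genotype:
    return Genotype(
        sample=d["sample"],
        marker=d["marker"],
        alleles=[(s, n) for s, n in d["alleles"]],
        additional_fragments=[(s, n) for s, n in d["additional_fragments"]],
        status=d["status"],
        notes=d["notes"],
    )


def _folder_to_json(f: Folder) -> dict:
    return {
        "name": f.name,
        "samples": f.samples,
        "subfolders": [_folder_to_json(s) for s in f.subfolders],
    }


def _folder_from_json(d: dict) -> Folder:
    return Folder(
        name=d["name"],
        samples=list(d["samples"]),
        subfolders=[_folder_from_json(s) for s in d["subfolders"]],
    )


def save_project(project: Project, path: str | Path, embed_fsa: bool = False) -> None:
    """Write the project as JSON; ``embed_fsa`` inlines the chromatogram
    files base64-encoded so the archive is self-contained."""
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "folders": _folder_to_json(project.root),
        "standards": [
            {"name": s.name, "sizes": list(s.sizes)}
            for s in project.standards.values()
        ],
        "panels": [
            {
                "name": p.name,
                "markers": [
                    {
                        "name": m.name, "channel": m.channel, "ploidy": m.ploidy,
                        "motif_length": m.motif_length,
                        "range_start": m.range_start, "range_end": m.range_end,
                        "bins": [
                            {"name": b.name, "start": b.start, "end": b.end}
                            for b in m.bins
                        ],
                    }
                    for m in p.markers
                ],
            }
            for p in project.panels.values()
        ],
        "samples": [],
        "genotypes": [_genotype_to_json(g) for g in project.genotypes.values()],
    }
    for s in project.samples.values():
        entry = {
            "name": s.name,
            "path": s.path,
            "plate": s.plate,
            "well": s.well,
            "run_date": s.run_date.isoformat() if s.run_date else None,
            "quality": s.quality,
            "panel": s.panel,
            "offsets": {m: [o.a, o.b] for m, o in s.offsets.items()},
            "fit": _fit_to_json(s.fit) if s.fit else None,
        }
        if embed_fsa and s.path:
            entry["fsa_base64"] = base64.b64encode(
                Path(s.path).read_bytes()
            ).decode("ascii")
        doc["samples"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_project(
    path: str | Path, into: Project | None = None, fsa_dir: str | Path | None = None
) -> Project:
    """Load a project JSON file.

    With ``into`` given, archive contents merge into an existing
    project: panels and standards already present *by name* are kept
    (a name collision with different content is an error).  Embedded
    chromatograms are materialised under ``fsa_dir`` (default:
    alongside the project file).
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != FORMAT_NAME:
        raise ValueError(f"not a {FORMAT_NAME} file")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"project version {doc.get('version')} needs migration; "
            f"this build reads version {FORMAT_VERSION}"
        )
    project = into if into is not None else Project()
    for sd in doc["standards"]:
        std = SizeStandard(sd["name"], tuple(sd["sizes"]))
        if sd["name"] in project.standards:
            if project.standards[sd["name"]].sizes != std.sizes:
                raise ValueError(
                    f"standard '{sd['name']}' already exists with different sizes"
                )
        else:
            project.standards[sd["name"]] = std
    for pd in doc["panels"]:
        panel = Panel(
            name=pd["name"],
            markers=[
                Marker(
                    name=md["name"], channel=md["channel"], ploidy=md["ploidy"],
                    motif_length=md["motif_length"],
                    range_start=md["range_start"], range_end=md["range_end"],
                    bins=[Bin(bd["name"], bd["start"], bd["end"])
                          for bd in md["bins"]],
                )
                for md in pd["markers"]
            ],
        )
        if pd["name"] in project.panels:
            existing = project.panels[pd["name"]]
            if [m.name for m in existing.markers] != [m.name for m in panel.markers]:
                raise ValueError(
                    f"panel '{pd['name']}' already exists with different markers"
                )
        else:
            project.panels[pd["name"]] = panel
    if into is None:
        project.root = _folder_from_json(doc["folders"])
    else:
        project.root.subfolders.append(_folder_from_json(doc["folders"]))
    for sd in doc["samples"]:
        sample = Sample(
            name=sd["name"],
            path=sd["path"],
            plate=sd["plate"],
            well=sd["well"],
            run_date=(datetime.date.fromisoformat(sd["run_date"])
                      if sd["run_date"] else None),
            quality=sd["quality"],
            panel=sd["panel"],
            offsets={m: OffsetParams(a, b)
                     for m, (a, b) in sd["offsets"].items()},
            fit=_fit_from_json(sd["fit"]) if sd["fit"] else None,
        )
        if "fsa_base64" in sd:
            out_dir = Path(fsa_dir) if fsa_dir else Path(path).parent
            out_dir.mkdir(parents=True, exist_ok=True)
            target = out_dir / f"{sample.name}.fsa"
            target.write_bytes(base64.b64decode(sd["fsa_base64"]))
            sample.path = str(target)
        project.samples[sample.name] = sample
    for gd in doc["genotypes"]:
        gt = _genotype_from_json(gd)
        project.genotypes[(gt.sample, gt.marker)] = gt
    return project
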