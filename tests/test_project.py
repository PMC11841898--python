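"""Project container: import, sizing/panel application, filtering,
export and JSON persistence."""

import json

import numpy as np
import pytest

from msatcall.abif import write_fsa
from msatcall.calling import Genotype
from msatcall.panels import OffsetParams, Panel
from msatcall.project import (
    Project,
    Sample,
    apply_panel,
    apply_standard,
    call_genotypes,
    export_genotypes,
    filter_genotypes,
    filter_samples,
    import_samples,
    load_project,
    normalize_well,
    save_project,
)
from msatcall.sizing import SizeStandard, get_standard
from msatcall.synth import SynthSpec, default_panel, generate_plate


@pytest.fixture(scope="module")
def plate_dir(tmp_path_factory):
    """Eight synthetic FSA files plus their ground truth."""
    d = tmp_path_factory.mktemp("plate")
    spec = SynthSpec(seed=77)
    plate = generate_plate(spec, 8)
    truths = {}
    for chrom, truth in plate:
        write_fsa(chrom, d / f"{truth.sample}.fsa")
        truths[truth.sample] = truth
    return d, truths


@pytest.fixture
def loaded_project(plate_dir):
    d, truths = plate_dir
    project = Project()
    report = import_samples(project, sorted(d.glob("*.fsa")))
    assert not report.failed
    apply_standard(project, get_standard("GeneScan-500"), degree=3)
    apply_panel(project, default_panel())
    return project, truths


class TestImport:
    def test_batch_import_counts_successes(self, plate_dir):
        d, _ = plate_dir
        project = Project()
        report = import_samples(project, sorted(d.glob("*.fsa")))
        assert len(report.succeeded) == 8 and not report.failed
        assert len(project.samples) == 8

    def test_corrupt_file_reported_not_fatal(self, plate_dir, tmp_path):
        d, _ = plate_dir
        bad = tmp_path / "corrupt.fsa"
        bad.write_bytes(b"ABIF" + b"\x00" * 10)
        project = Project()
        report = import_samples(project, sorted(d.glob("*.fsa")) + [bad])
        assert len(report.succeeded) == 8
        assert len(report.failed) == 1 and "corrupt" in report.failed[0][1]

    def test_import_order_does_not_change_state(self, plate_dir):
        d, _ = plate_dir
        paths = sorted(d.glob("*.fsa"))
        a, b = Project(), Project()
        import_samples(a, paths)
        import_samples(b, list(reversed(paths)))
        assert set(a.samples) == set(b.samples)
        for name in a.samples:
            assert a.samples[name].well == b.samples[name].well


class TestApply:
    def test_standard_application_sizes_every_sample(self, loaded_project):
        project, _ = loaded_project
        assert all(s.fit is not None for s in project.samples.values())
        assert all(s.quality > 0.9 for s in project.samples.values())

    def test_panel_application_initializes_product(self, loaded_project):
        project, _ = loaded_project
        assert len(project.genotypes) == 8 * len(default_panel().markers)

    def test_calling_recovers_truth(self, loaded_project):
        project, truths = loaded_project
        called = call_genotypes(project)
        markers = {m.name: m for m in default_panel().markers}
        hits = total = 0
        for gt in called:
            m = markers[gt.marker]
            got = sorted(round(s) for s, _ in gt.alleles)
            if m.ploidy == 2 and len(got) == 1:
                got = got * 2
            want = sorted(round(a) for a in truths[gt.sample].genotypes[m.name])
            total += 1
            hits += got == want
        assert hits / total >= 0.99

    def test_sabotaged_ladder_found_by_quality_filter(self, plate_dir):
        d, _ = plate_dir
        project = Project()
        import_samples(project, sorted(d.glob("*.fsa")))
        victim = sorted(project.samples)[3]
        chrom = project.samples[victim].load_chromatogram()
        chrom.channels[-1] = np.zeros_like(chrom.channels[-1])
        apply_standard(project, get_standard("GeneScan-500"))
        bad = filter_samples(project, [("quality", "<", 0.5)])
        assert [s.name for s in bad] == [victim]


class TestFilter:
    def test_empty_criteria_returns_everything(self, loaded_project):
        project, _ = loaded_project
        assert len(filter_samples(project, [])) == 8

    def test_unknown_field_lists_valid_ones(self, loaded_project):
        project, _ = loaded_project
        with pytest.raises(ValueError, match="quality"):
            filter_samples(project, [("qualty", "<", 0.5)])

    def test_allele_name_criterion_matches_truth(self, loaded_project):
        project, truths = loaded_project
        call_genotypes(project)
        target = "258"
        got = {
            (g.sample, g.marker)
            for g in filter_genotypes(project, [("allele_name", "==", target)])
        }
        markers = {m.name: m for m in default_panel().markers}
        want = set()
        for sname, truth in truths.items():
            for mname, alleles in truth.genotypes.items():
                if any(round(a) == 258 for a in alleles) \
                        and markers[mname].range_start <= 258 <= markers[mname].range_end:
                    want.add((sname, mname))
        assert got == want

    def test_or_combination(self, loaded_project):
        project, _ = loaded_project
        names = sorted(project.samples)
        got = filter_samples(
            project,
            [("name", "==", names[0]), ("name", "==", names[1])],
            combine="or",
        )
        assert sorted(s.name for s in got) == names[:2]


class TestExport:
    def test_row_count_and_header(self, loaded_project, tmp_path):
        project, _ = loaded_project
        call_genotypes(project)
        out = tmp_path / "genotypes.tsv"
        export_genotypes(project, list(project.genotypes.values()), out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 + len(project.genotypes)
        assert lines[0].split("\t")[:5] == ["sample", "plate", "well",
                                            "run_date", "marker"]

    def test_homozygote_duplicated_and_additional_column(self, tmp_path):
        project = Project()
        project.panels["p"] = default_panel()
        project.samples["s1"] = Sample(name="s1", plate="P", well="A01")
        gt = Genotype(sample="s1", marker="Ma",
                      alleles=[(258.0, "258")],
                      additional_fragments=[(266.0, "266")])
        project.genotypes[("s1", "Ma")] = gt
        out = tmp_path / "one.tsv"
        export_genotypes(project, [gt], out)
        header, row = out.read_text().splitlines()
        cols = dict(zip(header.split("\t"), row.split("\t")))
        assert cols["allele1"] == cols["allele2"] == "258"
        assert cols["size1"] == cols["size2"] == "258.00"
        assert cols["additional_fragments"] == "266.00:266"
        assert "266" not in (cols["allele1"], cols["allele2"])

    def test_export_is_deterministic(self, loaded_project, tmp_path):
        project, _ = loaded_project
        call_genotypes(project)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_genotypes(project, list(project.genotypes.values()), a)
        export_genotypes(project, list(project.genotypes.values()), b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_selection_rejected(self, loaded_project, tmp_path):
        project, _ = loaded_project
        with pytest.raises(ValueError, match="empty"):
            export_genotypes(project, [], tmp_path / "no.tsv")


class TestPersistence:
    def test_save_load_round_trip(self, loaded_project, tmp_path):
        project, _ = loaded_project
        call_genotypes(project)
        for s in project.samples.values():
            s.offsets["Ma"] = OffsetParams(-6.40, 1.029)
        path = tmp_path / "proj.json"
        save_project(project, path)
        back = load_project(path)
        assert set(back.samples) == set(project.samples)
        for name, s in project.samples.items():
            b = back.samples[name]
            assert (b.plate, b.well, b.panel) == (s.plate, s.well, s.panel)
            assert b.offsets["Ma"] == s.offsets["Ma"]
            assert b.quality == pytest.approx(s.quality)
            assert np.allclose(b.fit.coefficients, s.fit.coefficients)
        assert set(back.genotypes) == set(project.genotypes)
        for key, gt in project.genotypes.items():
            bgt = back.genotypes[key]
            assert bgt.alleles == gt.alleles
            assert bgt.additional_fragments == gt.additional_fragments
            assert (bgt.status, bgt.notes) == (gt.status, gt.notes)

    def test_standard_dedup_by_name_on_merge(self, loaded_project, tmp_path):
        project, _ = loaded_project
        path = tmp_path / "archive.json"
        save_project(project, path)
        dest = Project()
        dest.standards["GeneScan-500"] = get_standard("GeneScan-500")
        load_project(path, into=dest)
        assert list(dest.standards) == ["GeneScan-500"]

    def test_name_collision_with_different_content_is_an_error(
        self, loaded_project, tmp_path
    ):
        project, _ = loaded_project
        path = tmp_path / "archive.json"
        save_project(project, path)
        dest = Project()
        dest.standards["GeneScan-500"] = SizeStandard(
            "GeneScan-500", (10, 20, 30, 40)
        )
        with pytest.raises(ValueError, match="different sizes"):
            load_project(path, into=dest)

    def test_unknown_version_is_a_migration_error(self, tmp_path):
        path = tmp_path / "future.json"
        path.write_text(json.dumps({"format": "msatcall-project", "version": 99}))
        with pytest.raises(ValueError, match="migration"):
            load_project(path)

    def test_non_project_json_rejected(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text(json.dumps({"hello": 1}))
        with pytest.raises(ValueError, match="not a"):
            load_project(path)

    def test_embedded_archive_is_self_contained(self, loaded_project, tmp_path):
        project, _ = loaded_project
        path = tmp_path / "embedded.json"
        save_project(project, path, embed_fsa=True)
        back = load_project(path, fsa_dir=tmp_path / "fsa")
        name = sorted(back.samples)[0]
        chrom = back.samples[name].load_chromatogram()
        assert chrom.scan_count > 0


def test_well_normalization():
    assert normalize_well("a1") == "A01"
    assert normalize_well("H12") == "H12"
    assert normalize_well("B07") == "B07"
    assert normalize_well("weird") == "weird"
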