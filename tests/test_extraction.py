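import filecmp

import pytest

from contigscout.errors import InputError, ParameterError
from contigscout.extraction import (
    ContigProfile,
    ExtractionCriteria,
    rerun_from_blast,
    select_contigs,
    word_frequency_table,
    write_main_report,
    write_tophits_file,
)
from contigscout.pipeline import RunConfig, run
from contigscout.sequence_io import read_fasta
from contigscout.taxonomy import TaxLineage, parse_hit_table


def profile(contig_id, genus="GenX", n_orfs=4, **kwargs):
    lineage = TaxLineage.make(domain="Bacteria", genus=genus,
                              species=f"{genus} sp")
    defaults = dict(
        length=10_000, gc_percent=50.0, coding_density=1.0,
        n_orfs=n_orfs, n_orfs_with_hits=n_orfs,
        top_hit_taxa=[lineage] * n_orfs, mean_aai=85.0, coverage=10.0,
        cluster=1,
    )
    defaults.update(kwargs)
    return ContigProfile(contig_id=contig_id, **defaults)


class TestCriteriaValidation:
    def test_empty_criteria_rejected(self):
        with pytest.raises(ParameterError, match="at least one"):
            ExtractionCriteria()

    def test_taxon_without_rank_rejected(self):
        with pytest.raises(ParameterError):
            ExtractionCriteria(taxon="Pseudomonas")

    def test_inverted_range_rejected(self):
        with pytest.raises(ParameterError, match="gc"):
            ExtractionCriteria(gc_min=60, gc_max=40)

    def test_perc_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ExtractionCriteria(gc_max=50, perc=150)


class TestSelectContigs:
    def test_numeric_bounds_inclusive(self):
        profiles = [profile("a", gc_percent=50.0), profile("b", gc_percent=50.1)]
        matched, unmatched = select_contigs(
            profiles, ExtractionCriteria(gc_max=50.0)
        )
        assert matched == ["a"] and unmatched == ["b"]

    def test_all_active_criteria_must_hold(self):
        euk = TaxLineage.make(domain="Eukaryota", genus="Euk", species="E sp")
        profiles = [
            profile("euk_ok", gc_percent=42.0, coding_density=0.1),
            profile("euk_dense", gc_percent=42.0, coding_density=0.9),
            profile("bac", gc_percent=42.0, coding_density=0.3),
        ]
        # make the first two eukaryotic by top-hit domain
        from contigscout.taxonomy import HitGroup, HitRecord, summarize_contig
        for p, lin in zip(
            profiles,
            [euk, euk, TaxLineage.make(domain="Bacteria", genus="B",
                                       species="B sp")],
        ):
            hits = [
                HitRecord(f"{p.contig_id}_{i + 1}", "s", 80.0, 100, 1e-40,
                          400.0, "t", lin)
                for i in range(3)
            ]
            groups = [HitGroup.from_hits(h.orf_id, [h]) for h in hits]
            p.summary = summarize_contig(p.contig_id, groups, 3)
            p.top_hit_taxa = [lin] * 3
        criteria = ExtractionCriteria(
            taxon="Eukaryota", rank="domain", gc_max=50.0, density_max=0.5
        )
        matched, unmatched = select_contigs(profiles, criteria)
        assert matched == ["euk_ok"]
        assert set(unmatched) == {"euk_dense", "bac"}

    def test_partition_is_exact(self):
        profiles = [profile(f"c{i}", gc_percent=30 + i) for i in range(10)]
        matched, unmatched = select_contigs(
            profiles, ExtractionCriteria(gc_max=34.0)
        )
        assert sorted(matched + unmatched) == sorted(p.contig_id
                                                     for p in profiles)
        assert not set(matched) & set(unmatched)

    def test_coverage_criterion_requires_depth(self):
        profiles = [profile("a", coverage=None)]
        with pytest.raises(ParameterError, match="coverage"):
            select_contigs(profiles, ExtractionCriteria(coverage_min=5.0))

    def test_missing_values_fail_their_criteria(self):
        profiles = [profile("all_n", gc_percent=None),
                    profile("fine", gc_percent=40.0)]
        matched, _ = select_contigs(profiles, ExtractionCriteria(gc_max=50.0))
        assert matched == ["fine"]

    def test_narrowing_ranges_shrinks_matched_set(self):
        profiles = [profile(f"c{i}", gc_percent=30.0 + 2 * i)
                    for i in range(10)]
        wide, _ = select_contigs(profiles, ExtractionCriteria(gc_min=30,
                                                              gc_max=48))
        narrow, _ = select_contigs(profiles, ExtractionCriteria(gc_min=34,
                                                                gc_max=42))
        assert set(narrow) <= set(wide)

    def test_cluster_criterion(self):
        profiles = [profile("a", cluster=1), profile("b", cluster=2),
                    profile("c", cluster=None)]
        matched, _ = select_contigs(profiles,
                                    ExtractionCriteria(clusters={1}))
        assert matched == ["a"]


class TestMainReport:
    def test_one_row_per_contig_and_na_rendering(self, tmp_path):
        profiles = [
            profile("a"),
            profile("b", coverage=None, mean_aai=None, cluster=None,
                    gc_percent=None, top_hit_taxa=[], n_orfs_with_hits=0),
        ]
        out = tmp_path / "report.csv"
        write_main_report(profiles, out)
        lines = out.read_text().splitlines()
        assert lines[0] == (
            "contig,length,gc,coding_density,mean_aai,coverage,cluster,"
            "n_orfs,n_orfs_with_hits,top_hit_taxa"
        )
        assert len(lines) == 3
        row_b = lines[2].split(",")
        assert row_b[2] == row_b[4] == row_b[5] == row_b[6] == "NA"
        assert row_b[9] == "NA"

    def test_taxa_column_uses_requested_rank(self, tmp_path):
        out = tmp_path / "report.csv"
        write_main_report([profile("a", genus="Pseudomonas", n_orfs=2)], out,
                          rank="domain")
        assert out.read_text().splitlines()[1].endswith("Bacteria;Bacteria")

    def test_regeneration_is_byte_identical(self, tmp_path):
        profiles = [profile(f"c{i}") for i in range(5)]
        p1, p2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        write_main_report(profiles, p1)
        write_main_report(profiles, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestTophitsFile:
    def test_round_trips_through_parser(self, tmp_path, small_community):
        groups = parse_hit_table(small_community.hits)
        out = tmp_path / "top.tsv"
        write_tophits_file(groups, out, n=100)
        assert parse_hit_table(out) == groups

    def test_n_one_keeps_top_hit_only(self, tmp_path, small_community):
        groups = parse_hit_table(small_community.hits)
        out = tmp_path / "top1.tsv"
        write_tophits_file(groups, out, n=1)
        back = parse_hit_table(out)
        assert all(len(g.hits) == 1 for g in back.values())
        assert all(back[o].top() == g.top() for o, g in groups.items())


class TestWordFrequency:
    def test_coverage_weighting(self):
        profiles = [
            profile("c1", genus="GenA", n_orfs=1, coverage=10.0),
            profile("c2", genus="GenB", n_orfs=1, coverage=30.0),
        ]
        table = word_frequency_table(profiles, depth={"c1": 10.0, "c2": 30.0})
        assert table == pytest.approx({"GenA": 0.25, "GenB": 0.75})

    def test_without_depth_plain_counts(self):
        profiles = [
            profile("c1", genus="GenA", n_orfs=3),
            profile("c2", genus="GenB", n_orfs=1),
        ]
        table = word_frequency_table(profiles)
        assert table == pytest.approx({"GenA": 0.75, "GenB": 0.25})

    def test_weights_sum_to_one(self, small_community):
        config = RunConfig(
            fasta=str(small_community.fasta), blast=str(small_community.hits),
            out_prefix=str(small_community.fasta.parent / "wf"),
        )
        result = run(config)
        table = word_frequency_table(result.profiles)
        assert sum(table.values()) == pytest.approx(1.0)


class TestRerunFromBlast:
    def _config(self, mc, tmp_path, name, **kw):
        return RunConfig(
            fasta=str(mc.fasta), blast=str(mc.hits),
            out_prefix=str(tmp_path / name), depth=str(mc.depth),
            markers=str(mc.markers), genus="Alphagenus", fa=True, hgt=True,
            **kw,
        )

    def test_outputs_byte_identical_to_full_run(self, tmp_path,
                                                small_community):
        res1 = run(self._config(small_community, tmp_path, "full"))
        res2 = rerun_from_blast(
            str(small_community.fasta), str(small_community.hits),
            str(tmp_path / "rerun"),
            criteria=ExtractionCriteria(taxon="Alphagenus", rank="genus"),
            depth=str(small_community.depth),
            markers=str(small_community.markers), fa=True, hgt=True,
        )
        for key in ("main", "hgt", "matched", "unmatched", "tophits",
                    "wordfreq"):
            assert filecmp.cmp(res1.outputs[key], res2.outputs[key],
                               shallow=False), key

    def test_tighter_perc_shrinks_matched_set(self, tmp_path,
                                              small_community):
        loose = run(self._config(small_community, tmp_path, "loose",
                                 perc=30.0))
        tight = run(self._config(small_community, tmp_path, "tight",
                                 perc=90.0))
        assert set(tight.matched) <= set(loose.matched)

    def test_missing_blast_is_input_error(self, tmp_path, small_community):
        with pytest.raises(InputError):
            rerun_from_blast(
                str(small_community.fasta), str(tmp_path / "ghost.blast"),
                str(tmp_path / "x"),
                criteria=ExtractionCriteria(gc_max=50.0),
            )

    def test_matched_fasta_holds_planted_genome(self, tmp_path,
                                                small_community):
        res = run(self._config(small_community, tmp_path, "planted"))
        matched = read_fasta(res.outputs["matched"])
        assert {r.contig_id for r in matched} == {
            c for c, g in small_community.truth.items() if g == "GenomeA"
        }
        unmatched = read_fasta(res.outputs["unmatched"])
        all_ids = {r.contig_id for r in matched} | {
            r.contig_id for r in unmatched
        }
        assert all_ids == set(small_community.truth)
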