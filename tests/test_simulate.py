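import numpy as np
import pandas as pd
import pytest

from breakscape import io as bsio
from breakscape.bless import deduplicate_fragments
from breakscape.core import GenomicInterval, count_fragments_in_window
from breakscape.simulate import (
    FeatureSpec,
    SimulationConfig,
    fragments_to_pairs,
    make_genome,
    simulate_bless,
    simulate_chip,
    write_fixture_bundle,
)


def tiny_config(**overrides):
    defaults = dict(
        seed=1,
        chrom_spec={"chr1": 1_000_000, "chrY": 100_000},
        n_candidate_sites=12,
        n_cleaved=4,
        n_hr=1,
        n_nhej=1,
        feature_specs=[FeatureSpec("f", "increase", 4.0, 1000, "all")],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_label_counts_must_fit_cleaved(self):
        with pytest.raises(ValueError, match="n_hr"):
            tiny_config(n_hr=3, n_nhej=2)

    def test_chry_required(self):
        with pytest.raises(ValueError, match="chrY"):
            tiny_config(chrom_spec={"chr1": 1_000_000})

    def test_efficiency_range_in_unit_interval(self):
        with pytest.raises(ValueError):
            tiny_config(cleavage_efficiency_range=(0.0, 1.0))


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        a = make_genome(tiny_config())
        b = make_genome(tiny_config())
        assert a[0] == b[0]
        assert a[1].to_frame().equals(b[1].to_frame())
        assert a[2].table.equals(b[2].table)

    def test_site_structure(self):
        cs, sites, truth = make_genome(tiny_config())
        assert len(sites) == 12
        chroms = pd.Series([s.chrom for s in sites])
        assert (chroms == "chrY").sum() == 2
        # min spacing respected per chromosome
        df = sites.to_frame().sort_values(["chrom", "position"])
        gaps = df.groupby("chrom")["position"].diff().dropna()
        assert (gaps >= 20_000).all()
        assert truth.table["cleaved"].sum() == 4
        assert set(truth.table["pathway"]) <= {"HR", "NHEJ", "none"}

    def test_pathway_labels_on_highest_efficiency_sites(self):
        cs, sites, truth = make_genome(tiny_config(n_cleaved=6, n_hr=2, n_nhej=2))
        t = truth.table[truth.table.cleaved].sort_values("efficiency", ascending=False)
        labelled = t.head(4)["pathway"]
        assert set(labelled) == {"HR", "NHEJ"}
        assert (t.tail(2)["pathway"] == "none").all()

    def test_no_cleavage_requested(self):
        _, _, truth = make_genome(tiny_config(n_cleaved=0, n_hr=0, n_nhej=0))
        assert not truth.table["cleaved"].any()

    def test_spacing_infeasible_raises(self):
        with pytest.raises(ValueError, match="too small|rejection"):
            make_genome(
                tiny_config(chrom_spec={"chr1": 100_000, "chrY": 100_000},
                            n_candidate_sites=30, n_cleaved=0, n_hr=0, n_nhej=0)
            )


class TestSimulateBless:
    def test_zero_rates_give_zero_fragments(self):
        cfg = tiny_config(background_rate=0.0, n_cleaved=0, n_hr=0, n_nhej=0)
        cs, sites, truth = make_genome(cfg)
        assert len(simulate_bless(cfg, cs, sites, truth)) == 0

    def test_deterministic_under_seed(self):
        cfg = tiny_config()
        cs, sites, truth = make_genome(cfg)
        a = simulate_bless(cfg, cs, sites, truth)
        b = simulate_bless(cfg, cs, sites, truth)
        assert a.equals(b)

    def test_site_window_count_matches_poisson_mean(self):
        # single fully cleaved site, depth 200: MC mean within 3 SE of 200
        counts = []
        for seed in range(50):
            cfg = tiny_config(
                seed=seed, background_rate=0.0, n_candidate_sites=3,
                n_cleaved=1, n_hr=0, n_nhej=0,
                cleavage_efficiency_range=(1.0, 1.0),
                aberrant_frac=0.0, duplicate_rate=0.0,
            )
            cs, sites, truth = make_genome(cfg)
            frags = simulate_bless(cfg, cs, sites, truth)
            (site_id,) = truth.cleaved_ids()
            site = next(s for s in sites if s.site_id == site_id)
            iv = GenomicInterval(site.chrom, site.position - 500, site.position + 500)
            counts.append(count_fragments_in_window(frags, iv))
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 200) < 3 * se + 1e-9

    def test_background_count_concentrates_around_rate(self):
        cfg = tiny_config(n_cleaved=0, n_hr=0, n_nhej=0, duplicate_rate=0.0)
        hits = 0
        for seed in range(10):
            c = tiny_config(seed=seed, n_cleaved=0, n_hr=0, n_nhej=0,
                            duplicate_rate=0.0)
            cs, sites, truth = make_genome(c)
            frags = simulate_bless(c, cs, sites, truth)
            lam = c.background_rate * 1_000_000
            n = (frags["chrom"] == "chr1").sum()
            if abs(n - lam) <= 4 * np.sqrt(lam):
                hits += 1
        assert hits >= 9

    def test_duplicate_rate_collapses_on_dedup(self):
        cfg = tiny_config(seed=3, duplicate_rate=0.5, aberrant_frac=0.0)
        cs, sites, truth = make_genome(cfg)
        frags = simulate_bless(cfg, cs, sites, truth)
        unique = deduplicate_fragments(frags)
        # duplicated records double: unique / emitted ~ 1 / 1.5
        ratio = len(unique) / len(frags)
        assert ratio == pytest.approx(1 / 1.5, rel=0.05)

    def test_aberrant_fraction_has_long_fragments(self):
        cfg = tiny_config(seed=5, aberrant_frac=0.2)
        cs, sites, truth = make_genome(cfg)
        frags = simulate_bless(cfg, cs, sites, truth)
        lens = frags["end"] - frags["start"]
        frac = (lens > 500).mean()
        assert 0.1 < frac < 0.3
        assert lens.max() <= 2000

    def test_pairs_cover_fragment_ends(self):
        cfg = tiny_config()
        cs, sites, truth = make_genome(cfg)
        frags = simulate_bless(cfg, cs, sites, truth)
        pairs = fragments_to_pairs(frags)
        assert (pairs["start1"] == frags["start"]).all()
        assert (pairs["end2"] == frags["end"]).all()


class TestSimulateChip:
    def test_deterministic_and_specificity(self):
        cfg = tiny_config(
            n_cleaved=6, n_hr=2, n_nhej=2,
            feature_specs=[FeatureSpec("hrdec", "decrease", 4.0, 2000, "HR_only")],
        )
        cs, sites, truth = make_genome(cfg)
        d1, u1 = simulate_chip(cfg, cs, sites, truth, "hrdec")
        d2, u2 = simulate_chip(cfg, cs, sites, truth, "hrdec")
        for chrom in cs:
            assert np.array_equal(d1.values[chrom], d2.values[chrom])
            assert np.array_equal(u1.values[chrom], u2.values[chrom])

        by_id = {s.site_id: s for s in sites}

        def window_ratio(site_id):
            s = by_id[site_id]
            b0 = (s.position - 1000) // cfg.binsize
            b1 = (s.position + 1000) // cfg.binsize
            d = d1.values[s.chrom][b0:b1].sum()
            u = u1.values[s.chrom][b0:b1].sum()
            return (d + 1) / (u + 1)

        hr_ratios = [window_ratio(i) for i in truth.pathway_ids("HR")]
        nhej_ratios = [window_ratio(i) for i in truth.pathway_ids("NHEJ")]
        assert np.mean(hr_ratios) < 0.6          # fold-4 depletion
        assert 0.6 < np.mean(nhej_ratios) < 1.6  # untouched by construction

    def test_unknown_feature_rejected(self):
        cfg = tiny_config()
        cs, sites, truth = make_genome(cfg)
        with pytest.raises(KeyError):
            simulate_chip(cfg, cs, sites, truth, "nope")

    def test_zero_baseline_gives_zero_track_with_library_floor(self):
        cfg = tiny_config(
            feature_specs=[FeatureSpec("z", "increase", 2.0, 1000, "all",
                                       baseline_mean=0.0)]
        )
        cs, sites, truth = make_genome(cfg)
        d, u = simulate_chip(cfg, cs, sites, truth, "z")
        assert all((v == 0).all() for v in d.values.values())
        assert d.library_size == 1.0 and u.library_size == 1.0


class TestFixtureBundle:
    def test_bundle_round_trips_and_manifest_counts(self, tmp_path):
        cfg = tiny_config()
        manifest = write_fixture_bundle(cfg, tmp_path / "bundle")
        base = tmp_path / "bundle"
        cs = bsio.read_chromsizes(base / "chrom.sizes")
        sites = bsio.read_sites(base / "sites.bed")
        frags = bsio.read_fragments_bed(base / "fragments.bed")
        pairs = bsio.read_bedpe(base / "fragments.bedpe")
        track = bsio.read_coverage(base / "f.damaged.bedgraph", cs, cfg.binsize)
        assert len(sites) == cfg.n_candidate_sites
        assert len(frags) == len(pairs)
        rows = manifest.set_index("file")["rows"]
        assert rows["fragments.bed"] == len(frags)
        assert rows["sites.bed"] == len(sites)
        assert track.library_size > 0

    def test_same_seed_identical_bundles(self, tmp_path):
        cfg = tiny_config()
        m1 = write_fixture_bundle(cfg, tmp_path / "a")
        m2 = write_fixture_bundle(cfg, tmp_path / "b")
        assert m1.equals(m2)
        for name in m1["file"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
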