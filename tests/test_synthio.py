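"""Generator contracts: determinism, bounds, truth completeness, planted effects."""

import collections
import copy

import numpy as np
import pandas as pd
import pytest

from methomics import AuxSizes, MethylSimConfig, TruthManifest, synthio
from methomics.errors import ConfigError


@pytest.mark.parametrize(
    "field,value",
    [
        ("mean_coverage", 0.0),
        ("frac_hypo", 1.2),
        ("baseline_alpha", -1.0),
        ("hypo_tumor_mean", 1.5),
    ],
)
def test_invalid_config_names_offending_field(field, value):
    cfg = MethylSimConfig(**{field: value})
    with pytest.raises(ConfigError, match=field):
        synthio.simulate_methylome(cfg)


def test_fraction_sum_and_ordering_invariants_rejected():
    with pytest.raises(ConfigError):
        synthio.simulate_methylome(MethylSimConfig(frac_hypo=0.6, frac_hyper=0.6))
    with pytest.raises(ConfigError):
        synthio.simulate_methylome(
            MethylSimConfig(hypo_tumor_mean=0.9, hypo_normal_mean=0.2)
        )


def test_zero_cpgs_gives_empty_tables_and_truth():
    tables, truth = synthio.simulate_methylome(MethylSimConfig(n_cpgs=0))
    assert all(len(t) == 0 for t in tables.values())
    assert truth.cpg_class == {}


def test_zero_tumor_mean_yields_all_zero_counts_in_tumors():
    # Binomial(n, 0) is identically 0, so planted hypo CpGs must have no
    # methylated reads in any tumor sample regardless of coverage.
    cfg = MethylSimConfig(
        n_cpgs=200, n_tumor=2, n_normal=1, mean_coverage=500,
        frac_hypo=0.5, frac_hyper=0.0, hypo_tumor_mean=0.0, seed=9,
    )
    tables, truth = synthio.simulate_methylome(cfg)
    hypo_pos = {
        int(c.split(":")[1]) for c, cls in truth.cpg_class.items() if cls == "hypo"
    }
    assert hypo_pos
    for sample, group in truth.samples.items():
        if group != "tumor":
            continue
        t = tables[sample]
        on_hypo = t["pos"].isin(hypo_pos | {p + 1 for p in hypo_pos})
        assert (t.loc[on_hypo, "count_methylated"] == 0).all()


def test_seeded_determinism_is_byte_identical(tmp_path):
    cfg = MethylSimConfig(n_cpgs=500, frac_hypo=0.05, seed=7)
    for d in ("a", "b"):
        tables, _ = synthio.simulate_methylome(cfg)
        synthio.write_cytosine_reports(tables, tmp_path / d)
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_truth_ratios_and_realized_ratios_bounded(small_methylome):
    _, tables, truth = small_methylome
    for r in truth.cpg_group_ratio.values():
        assert 0.0 <= r["normal"] <= 1.0 and 0.0 <= r["tumor"] <= 1.0
    for t in tables.values():
        total = t["count_methylated"] + t["count_unmethylated"]
        assert (t["count_methylated"] <= total).all()


def test_truth_covers_every_emitted_cpg(small_methylome):
    _, tables, truth = small_methylome
    known = set()
    for c in truth.cpg_class:
        p = int(c.split(":")[1])
        known.update({p, p + 1})  # plus-strand C and its minus-strand partner
    for t in tables.values():
        assert set(t["pos"]).issubset(known)


def test_manifest_roundtrips_losslessly(tmp_path, small_methylome):
    _, _, truth = small_methylome
    p = tmp_path / "truth.json"
    truth.to_json(p)
    again = TruthManifest.from_json(p)
    assert again == truth


def test_group_means_converge_at_high_coverage():
    # with coverage >= 200 and >= 20 samples per group the empirical group
    # mean at planted CpGs is within 0.02 of the configured mean
    cfg = MethylSimConfig(
        n_cpgs=400, n_tumor=20, n_normal=20, mean_coverage=200,
        frac_hypo=0.25, frac_hyper=0.0, seed=77,
    )
    tables, truth = synthio.simulate_methylome(cfg)
    hypo_pos = {
        int(c.split(":")[1]) for c, cls in truth.cpg_class.items() if cls == "hypo"
    }
    for group, want in (("tumor", cfg.hypo_tumor_mean), ("normal", cfg.hypo_normal_mean)):
        meth = tot = 0
        for sample, g in truth.samples.items():
            if g != group:
                continue
            t = tables[sample]
            cpg = t["pos"].where(t["strand"] == "+", t["pos"] - 1)
            on = cpg.isin(hypo_pos)
            meth += t.loc[on, "count_methylated"].sum()
            tot += (t.loc[on, "count_methylated"] + t.loc[on, "count_unmethylated"]).sum()
        assert abs(meth / tot - want) < 0.02


def test_expression_noiseless_line_is_exact(small_methylome):
    _, _, truth0 = small_methylome
    truth = copy.deepcopy(truth0)
    fpkm, _, gene_map, truth = synthio.simulate_expression(
        truth, n_genes=50, n_driver=3, slope=-1.2, noise_sd=0.0, seed=5
    )
    drivers = [g for g, v in truth.genes.items() if v["driver"]]
    v = np.log10(fpkm + 1.0)
    for g in drivers:
        for group, ratio in (("tumor", 0.10), ("normal", 0.85)):
            cols = [s for s, grp in truth.samples.items() if grp == group]
            vals = v.loc[g, cols]
            assert np.allclose(vals, 2.5 - 1.2 * ratio, atol=1e-12)
            assert vals.nunique() == 1  # constant within group


def test_expression_zero_slope_zero_noise_constant(small_methylome):
    _, _, truth0 = small_methylome
    truth = copy.deepcopy(truth0)
    fpkm, _, _, truth = synthio.simulate_expression(
        truth, n_genes=50, n_driver=2, slope=0.0, noise_sd=0.0, seed=5
    )
    for g, meta in truth.genes.items():
        if meta["driver"]:
            assert fpkm.loc[g].nunique() == 1


def test_expression_determinism(small_methylome):
    _, _, truth0 = small_methylome
    frames = []
    for _ in range(2):
        truth = copy.deepcopy(truth0)
        _, de, _, _ = synthio.simulate_expression(truth, n_genes=50, n_driver=2, seed=3)
        frames.append(de)
    pd.testing.assert_frame_equal(frames[0], frames[1])


def test_expression_driver_overflow_rejected(small_methylome):
    _, _, truth0 = small_methylome
    truth = copy.deepcopy(truth0)
    with pytest.raises(ConfigError):
        synthio.simulate_expression(truth, n_genes=10, n_driver=11, seed=1)


def test_cohort_determinism_and_null_delta():
    classes = {"CN": 10, "GBM": 10, "LGG": 10}
    b1, l1, _ = synthio.simulate_cohort(300, classes, 20, 0.6, seed=8)
    b2, _, _ = synthio.simulate_cohort(300, classes, 20, 0.6, seed=8)
    pd.testing.assert_frame_equal(b1, b2)
    # delta 0: nothing stands out at any meaningful threshold
    beta, labels, _ = synthio.simulate_cohort(300, classes, 20, 0.0, seed=8)
    from methomics.cohort import specific_probes

    spec = specific_probes(beta, labels, "CN", threshold=0.2)
    assert int(spec["specific"].sum()) == 0


def test_cohort_planted_probes_are_top_ranked_by_bruteforce():
    # with large per-class n, the planted target-specific probes are exactly
    # the probes with the largest min target-vs-other-class mean difference
    classes = {"CN": 50, "GBM": 50, "LGG": 50}
    n_spec = 20
    beta, labels, truth = synthio.simulate_cohort(400, classes, n_spec, 0.6, seed=21)
    planted = {p for p, c in truth.probe_class.items() if c == "CN"}
    # brute force: per-probe min over other classes of |mean_CN - mean_c|
    diffs = {}
    for probe in beta.index:
        own = beta.loc[probe, [s for s in beta.columns if labels[s] == "CN"]].mean()
        others = [
            abs(own - beta.loc[probe, [s for s in beta.columns if labels[s] == c]].mean())
            for c in ("GBM", "LGG")
        ]
        diffs[probe] = min(others)
    top = set(sorted(diffs, key=lambda p: -diffs[p])[:n_spec])
    assert top == planted


def test_aux_sizes_zero_gives_empty_tables():
    v, f, c, _, truth = synthio.simulate_aux_tables(1, AuxSizes(0, 0, 0))
    assert len(v) == len(f) == len(c) == 0
    assert truth.variants["survivors"] == []


def test_aux_truth_marks_boundary_templates():
    v, f, c, coding, truth = synthio.simulate_aux_tables(1)
    per_row = truth.variants["per_row"]
    depth9 = v[v["total_depth"] == 9].iloc[0]["row_id"]
    assert per_row[depth9]["survives"] is False and "depth" in per_row[depth9]["reason"]
    af_row = v[(v["af_korean"] == 0.01)].iloc[0]["row_id"]
    assert per_row[af_row]["survives"] is False
    # the duplicated fusion survives exactly once in the truth key set
    dup = f[(f["gene_a"] == "CODB") & (f["gene_b"] == "NCX2")]
    assert len(dup) == 2
    key = synthio.fusion_key("CODB", "NCX2", "chr2", 1400, "chr3", 5400, 7, 2)
    assert truth.fusions["survivor_keys"].count(key) == 1
    counts = collections.Counter(truth.cnv.values())
    assert set(counts) == {"deletion", "neutral", "amplification"}
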