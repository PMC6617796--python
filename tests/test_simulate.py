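"""Synthetic-cohort generator: determinism, Hardy-Weinberg background,
closed-form founder-region concordance, and nearest-site lookup."""
from __future__ import annotations

import numpy as np
import pytest

from hetscan.io import HET, MISSING, write_vcf
from hetscan.popgen import het_near_disease, het_random
from hetscan.simulate import SimConfig, pseudo_disease_target, simulate_cohort


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(missing_rate=1.0)
    with pytest.raises(ValueError):
        SimConfig(founder_mode="bogus")
    with pytest.raises(ValueError):
        SimConfig(n_variants=0)
    with pytest.raises(ValueError):
        SimConfig(disease_pos=10**9).resolved_disease_site()


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(n_variants=400, n_chromosomes=2, seed=9)
    for name in ("a.vcf", "b.vcf"):
        matrix, _ = simulate_cohort(cfg)
        write_vcf(matrix, tmp_path / name)
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()
    other, _ = simulate_cohort(SimConfig(n_variants=400, n_chromosomes=2, seed=10))
    write_vcf(other, tmp_path / "c.vcf")
    assert (tmp_path / "a.vcf").read_bytes() != (tmp_path / "c.vcf").read_bytes()


def test_truth_is_consistent_with_matrix():
    cfg = SimConfig(n_variants=500, n_chromosomes=2, seed=4)
    matrix, truth = simulate_cohort(cfg)
    assert set(truth.carrier_status) == set(matrix.samples)
    assert sum(truth.carrier_status.values()) == cfg.n_carriers
    assert truth.disease_site.chrom == "chr1"
    assert truth.r_start <= truth.disease_site.pos <= truth.r_end
    # the disease site exists as a marker and carriers are heterozygous there
    row = np.where((matrix.chrom == "chr1") & (matrix.pos == truth.disease_site.pos))[0]
    assert len(row) == 1
    assert matrix.ids[row[0]] == "disease_u"
    carrier_cols = [i for i, s in enumerate(matrix.samples) if truth.carrier_status[s]]
    calls = matrix.calls[row[0], carrier_cols]
    assert set(calls[calls != MISSING]) <= {int(HET)}
    # per-chromosome maf vectors align with site counts
    for chrom, sl in matrix.blocks():
        assert len(truth.maf[chrom]) == sl.stop - sl.start
    # founder alleles recorded exactly for the non-disease markers in R
    in_r = (
        (matrix.chrom == "chr1")
        & (matrix.pos >= truth.r_start)
        & (matrix.pos <= truth.r_end)
        & (matrix.ids != "disease_u")
    )
    assert set(truth.founder_alleles) == set(matrix.pos[in_r].tolist())


def test_truth_json_roundtrip(tmp_path):
    _, truth = simulate_cohort(SimConfig(n_variants=50, n_chromosomes=1, seed=1))
    out = tmp_path / "truth.json"
    truth.to_json(out)
    import json

    payload = json.loads(out.read_text())
    assert payload["disease_site"]["pos"] == truth.disease_site.pos
    assert payload["config"]["seed"] == 1


def test_no_carrier_cohort_matches_hwe_expectation():
    """With no carriers every call is a Hardy-Weinberg draw: the genome-wide
    heterozygote count matches sum(2 f (1-f)) within 3 binomial SEs."""
    cfg = SimConfig(
        n_variants=10_000, n_chromosomes=1, n_carriers=0, n_noncarriers=10,
        missing_rate=0.05, include_disease_site=False, seed=21,
    )
    matrix, truth = simulate_cohort(cfg)
    f = np.array(truth.maf["chr1"])
    p = 2 * f * (1 - f)
    nonmiss = matrix.calls != MISSING
    het = matrix.calls == HET
    observed = het.sum()
    expected = (p[:, None] * nonmiss).sum()
    se = np.sqrt((p * (1 - p))[:, None].repeat(10, axis=1)[nonmiss].sum())
    assert abs(observed - expected) <= 3 * se


def test_carrier_het_matches_closed_form_inside_and_outside_r():
    """Carrier per-site heterozygosity: (1-f)/(1-e) inside the founder
    region, 2f(1-f) outside, each within 3 Monte-Carlo SEs."""
    e = 0.01
    # R spans the whole chromosome: every marker is a founder-region marker
    cfg_in = SimConfig(
        n_variants=10_000, n_chromosomes=1, chrom_length_bp=10_000_000,
        r_halfwidth_bp=10_000_000, n_carriers=20, n_noncarriers=0,
        disease_freq=e, missing_rate=0.0, include_disease_site=False, seed=33,
    )
    matrix, truth = simulate_cohort(cfg_in)
    f = np.array(truth.maf["chr1"])
    p_in = (1 - f) / (1 - e)
    observed = (matrix.calls == HET).sum()
    expected = p_in.sum() * 20
    se = np.sqrt((p_in * (1 - p_in)).sum() * 20)
    assert abs(observed - expected) <= 3 * se

    # tiny R: all but one marker behave as random Hardy-Weinberg markers
    cfg_out = SimConfig(
        n_variants=10_000, n_chromosomes=1, chrom_length_bp=10_000_000,
        r_halfwidth_bp=0, n_carriers=20, n_noncarriers=0,
        disease_freq=e, missing_rate=0.0, include_disease_site=False, seed=34,
    )
    matrix, truth = simulate_cohort(cfg_out)
    f = np.array(truth.maf["chr1"])
    outside = ~np.isin(matrix.pos, list(truth.founder_alleles))
    p_out = 2 * f[outside] * (1 - f[outside])
    observed = (matrix.calls[outside] == HET).sum()
    expected = p_out.sum() * 20
    se = np.sqrt((p_out * (1 - p_out)).sum() * 20)
    assert abs(observed - expected) <= 3 * se


def test_forced_minor_regime_matches_worked_example():
    """Fixed f = 0.1 with the founder carrying the minor allele: carrier
    per-site het ~ 0.9 inside R versus ~ 0.18 outside."""
    cfg = SimConfig(
        n_variants=4_000, n_chromosomes=1, chrom_length_bp=4_000_000,
        maf_distribution=("fixed", 0.1), r_halfwidth_bp=1_000_000,
        n_carriers=10, n_noncarriers=0, disease_freq=0.001,
        missing_rate=0.0, include_disease_site=False, seed=5,
    )
    matrix, truth = simulate_cohort(cfg)
    in_r = np.isin(matrix.pos, list(truth.founder_alleles))
    het = matrix.calls == HET
    het_in = het[in_r].mean()
    het_out = het[~in_r].mean()
    assert het_in == pytest.approx(het_near_disease(0.001, 0.1), abs=0.02)
    assert het_out == pytest.approx(het_random(0.1), abs=0.02)


def test_random_founder_mode_has_no_mean_elevation():
    """Drawing the founder allele from the population frequency is a
    structured null: expected heterozygosity inside R stays at 2f(1-f)."""
    cfg = SimConfig(
        n_variants=6_000, n_chromosomes=1, chrom_length_bp=6_000_000,
        maf_distribution=("fixed", 0.1), r_halfwidth_bp=3_000_000,
        n_carriers=20, n_noncarriers=0, disease_freq=0.001,
        founder_mode="random", missing_rate=0.0,
        include_disease_site=False, seed=6,
    )
    matrix, truth = simulate_cohort(cfg)
    in_r = np.isin(matrix.pos, list(truth.founder_alleles))
    het_in = (matrix.calls[in_r] == HET).mean()
    assert het_in == pytest.approx(het_random(0.1), abs=0.02)


def test_r_truncated_at_chromosome_end():
    cfg = SimConfig(
        n_variants=200, n_chromosomes=1, chrom_length_bp=1_000_000,
        disease_pos=50_000, r_halfwidth_bp=500_000, seed=2,
    )
    _, truth = simulate_cohort(cfg)
    assert truth.r_start == 1
    assert truth.r_end == 550_000


def test_pseudo_disease_target_nearest_and_ties(default_cohort):
    matrix, _ = default_cohort
    chrom, sl = next(iter(matrix.blocks()))
    pos = matrix.pos[sl]
    # exact hit returns the site itself
    assert pseudo_disease_target(matrix, chrom, int(pos[10])).pos == int(pos[10])
    # linear-scan oracle on random queries
    rng = np.random.default_rng(0)
    for q in rng.integers(1, matrix.pos[sl].max() + 10_000, size=25):
        got = pseudo_disease_target(matrix, chrom, int(q)).pos
        dists = np.abs(pos.astype(np.int64) - int(q))
        best = pos[dists == dists.min()].min()
        assert got == int(best)
    with pytest.raises(KeyError):
        pseudo_disease_target(matrix, "chrMT", 5)


def test_noncarrier_scan_has_no_localized_peak():
    """In a no-carrier cohort the region R is nothing special: the max H
    over the R-width window at the disease position is not stochastically
    larger than over random same-width windows (permutation check)."""
    from hetscan.stage1 import WindowConfig, compute_htrack

    matrix, truth = simulate_cohort(
        SimConfig(n_carriers=0, n_noncarriers=4, n_chromosomes=2, seed=19)
    )
    track = compute_htrack(matrix, WindowConfig(m=50))
    on_chrom = track.chrom == truth.disease_site.chrom
    pos = track.pos[on_chrom]
    H = track.H[on_chrom]
    width = truth.r_end - truth.r_start

    def window_max(start):
        sel = (pos >= start) & (pos <= start + width)
        return H[sel].max() if sel.any() else -np.inf

    observed = window_max(truth.r_start)
    rng = np.random.default_rng(3)
    starts = rng.integers(pos.min(), pos.max() - width, size=200)
    null_max = np.array([window_max(s) for s in starts])
    p = (1 + np.sum(null_max >= observed)) / (len(starts) + 1)
    assert p > 0.05


def test_pseudo_disease_target_midpoint_tie_takes_lower_pos():
    from conftest import make_matrix

    m = make_matrix(np.full((3, 1), int(HET)), start=100, step=200)  # 100,300,500
    assert pseudo_disease_target(m, "chr1", 200).pos == 100
    assert pseudo_disease_target(m, "chr1", 400).pos == 300
    assert pseudo_disease_target(m, "chr1", 401).pos == 500
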