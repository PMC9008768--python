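"""Genotype QC, HWE exact test, IBS/MDS and LD utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from rvscca import (
    LinkageRegionTable,
    fill_missing,
    hwe_exact_pvalue,
    ibs_distance,
    ld_blocks,
    ld_r2,
    mds_coordinates,
    qc_filter,
    restrict_to_regions,
)
from conftest import make_genotypes


# ---------------------------------------------------------------- HWE

def hwe_pvalue_enumeration(n_aa, n_ab, n_bb):
    """Independent oracle: direct probability enumeration with binomials."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_bb + n_ab, 2 * n_aa + n_ab)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # multinomial count of genotype tables x 2^het, over allele-count ways
        probs[h] = (
            comb(n, hom_rare, exact=True)
            * comb(n - hom_rare, h, exact=True)
            * 2**h
            / (comb(2 * n, rare, exact=True))
        )
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return sum(p / total for p in probs.values() if p / total <= obs + 1e-12)


@pytest.mark.parametrize(
    "counts",
    [(1, 2, 1), (4, 0, 0), (0, 4, 0), (10, 5, 2), (25, 3, 2), (12, 12, 6), (0, 30, 0)],
)
def test_hwe_matches_full_enumeration(counts):
    assert hwe_exact_pvalue(*counts) == pytest.approx(
        hwe_pvalue_enumeration(*counts), rel=1e-10
    )


def test_hwe_modal_table_has_pvalue_one():
    # (1, 2, 1) sits exactly at the HWE expectation for allele freq 1/2
    assert hwe_exact_pvalue(1, 2, 1) == pytest.approx(1.0)


def test_hwe_all_heterozygote_is_extreme_but_proper():
    p = hwe_exact_pvalue(0, 4, 0)
    assert 0.0 < p < 1.0


def test_hwe_monomorphic_is_certain():
    assert hwe_exact_pvalue(7, 0, 0) == pytest.approx(1.0)


def test_hwe_rejects_empty_table():
    with pytest.raises(ValueError):
        hwe_exact_pvalue(0, 0, 0)


@given(
    n_aa=st.integers(0, 15), n_ab=st.integers(0, 15), n_bb=st.integers(0, 15)
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_hwe_agrees_with_oracle_on_random_tables(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    assert hwe_exact_pvalue(n_aa, n_ab, n_bb) == pytest.approx(
        hwe_pvalue_enumeration(n_aa, n_ab, n_bb), rel=1e-9
    )


# ---------------------------------------------------------------- QC

def toy_qc_matrix():
    """5 SNPs with known fates under the default filters."""
    rng = np.random.default_rng(0)
    n = 100
    cols = {}
    # rs0: healthy, MAF ~0.3, HWE-consistent
    cols["rs0"] = rng.binomial(2, 0.3, size=n).astype(float)
    # rs1: monomorphic -> MAF filter
    cols["rs1"] = np.zeros(n)
    # rs2: 6% missing -> call-rate filter
    c = rng.binomial(2, 0.4, size=n).astype(float)
    c[:6] = np.nan
    cols["rs2"] = c
    # rs3: extreme heterozygote deficit -> HWE filter (all hom: 50/50 split)
    cols["rs3"] = np.array([0.0] * 50 + [2.0] * 50)
    # rs4: MAF just below 5%
    cols["rs4"] = np.array([1.0] * 9 + [0.0] * 91)
    return make_genotypes(np.column_stack(list(cols.values())))


def test_qc_filter_matches_hand_enumeration():
    g = toy_qc_matrix()
    out, report = qc_filter(g)
    assert list(out.snp_ids) == ["rs0"]
    assert report.dropped_call_rate == 1     # rs2 (6% missing)
    assert report.dropped_maf == 2           # rs1 (monomorphic), rs4 (MAF 4.5%)
    assert report.dropped_hwe == 1           # rs3 (no heterozygotes)


def test_qc_filter_is_idempotent():
    g = toy_qc_matrix()
    once, _ = qc_filter(g)
    twice, rep2 = qc_filter(once)
    np.testing.assert_array_equal(once.values, twice.values)
    assert rep2.dropped_call_rate == rep2.dropped_maf == rep2.dropped_hwe == 0


def test_qc_all_dropped_raises():
    g = make_genotypes(np.zeros((20, 2)))
    with pytest.raises(ValueError, match="all SNPs removed"):
        qc_filter(g)


def test_fill_missing_uses_rounded_snp_mean():
    g = make_genotypes(np.array([[0.0, 2], [1, 2], [1, 2], [np.nan, 2]]))
    filled = fill_missing(g)
    assert filled.values[3, 0] == 1.0  # round(2/3) = 1
    assert np.isfinite(filled.values).all()


def test_fill_missing_identity_when_complete():
    g = make_genotypes(np.array([[0.0, 1], [2, 1]]))
    np.testing.assert_array_equal(fill_missing(g).values, g.values)


# ---------------------------------------------------------------- regions

REGIONS = LinkageRegionTable(
    pd.DataFrame(
        {"chrom": [1, 10], "band": ["p31.1-q31.1", "p14-q24"],
         "start_mb": [83.0, 10.0], "end_mb": [185.0, 100.0]}
    )
)


def test_region_restriction_keeps_interior_and_boundary_drops_outside():
    g = make_genotypes(
        np.tile([[0.0, 1, 2, 0]], (3, 1)),
        chrom=[1, 1, 1, 10],
        bp=[100_000_000, 83_000_000, 82_999_999, 200_000_000],
    )
    out = restrict_to_regions(g, REGIONS)
    assert list(out.snp_ids) == ["rs0", "rs1"]  # interior + exact closed boundary
    assert list(out.snps["region"]) == ["1p31.1-q31.1"] * 2


def test_region_restriction_drops_sex_chromosomes():
    g = make_genotypes(np.tile([[1.0, 1]], (3, 1)), chrom=["X", 1],
                       bp=[100_000_000, 100_000_000])
    out = restrict_to_regions(g, REGIONS)
    assert list(out.snp_ids) == ["rs1"]


def test_region_table_validates_autosomes():
    with pytest.raises(ValueError, match="autosomal"):
        LinkageRegionTable(pd.DataFrame(
            {"chrom": [23], "band": ["q1"], "start_mb": [1.0], "end_mb": [2.0]}
        ))


# ---------------------------------------------------------------- IBS / MDS

def test_ibs_distance_toy_case_matches_hand_computation():
    g = make_genotypes(np.array([[0.0, 1], [2, 1], [0, 0]]))
    D = ibs_distance(g)
    # pairs: (0,1): |0-2|+|1-1| = 2 -> 2/(2*2) = 0.5; (0,2): 1/4; (1,2): 3/4
    expected = np.array([[0, 0.5, 0.25], [0.5, 0, 0.75], [0.25, 0.75, 0]])
    np.testing.assert_allclose(D, expected)


def test_ibs_extremes():
    g = make_genotypes(np.array([[0.0, 0, 0], [0, 0, 0], [2, 2, 2]]))
    D = ibs_distance(g)
    assert D[0, 1] == 0.0
    assert D[0, 2] == 1.0
    assert (D >= 0).all() and (D <= 1).all() and np.allclose(D, D.T)


def test_mds_recovers_euclidean_configuration():
    rng = np.random.default_rng(1)
    pts = rng.standard_normal((12, 3))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    coords = mds_coordinates(D, d=3)
    D2 = np.linalg.norm(coords.coords[:, None] - coords.coords[None, :], axis=2)
    np.testing.assert_allclose(D, D2, atol=1e-8)
    assert coords.explained_fraction == pytest.approx(1.0)
    np.testing.assert_allclose(coords.coords.mean(axis=0), 0.0, atol=1e-10)


def test_mds_rotation_equivariance_preserves_distances():
    rng = np.random.default_rng(2)
    pts = rng.standard_normal((10, 4))
    Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
    D1 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    D2 = np.linalg.norm((pts @ Q)[:, None] - (pts @ Q)[None, :], axis=2)
    c1 = mds_coordinates(D1, d=4).coords
    c2 = mds_coordinates(D2, d=4).coords
    G1 = np.linalg.norm(c1[:, None] - c1[None, :], axis=2)
    G2 = np.linalg.norm(c2[:, None] - c2[None, :], axis=2)
    np.testing.assert_allclose(G1, G2, atol=1e-8)


def test_mds_all_equal_points_give_zero_coordinates():
    D = np.zeros((5, 5))
    with pytest.warns(UserWarning, match="padding"):
        coords = mds_coordinates(D, d=2)
    np.testing.assert_allclose(coords.coords, 0.0)


def test_mds_unit_square_eigenvalues():
    # 4 points on a unit square: centered Gram matrix has eigenvalues
    # (1/2, 1/2, 0, 0) -- each axis carries variance n * 1/4 / 2... derived
    # by direct eigendecomposition of the doubly-centered -D^2/2.
    pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    coords = mds_coordinates(D, d=2)
    np.testing.assert_allclose(sorted(coords.eigenvalues), [1.0, 1.0], atol=1e-10)
    D2 = np.linalg.norm(coords.coords[:, None] - coords.coords[None, :], axis=2)
    np.testing.assert_allclose(D, D2, atol=1e-10)


# ---------------------------------------------------------------- LD

def test_ld_r2_self_is_one_and_toy_matches_pearson():
    g = make_genotypes(np.array([[0.0, 0], [1, 1], [1, 2], [2, 2]]))
    assert ld_r2(g, 0, 0) == pytest.approx(1.0)
    x, y = g.values[:, 0], g.values[:, 1]
    assert ld_r2(g, 0, 1) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)


def test_ld_r2_monomorphic_signalled():
    g = make_genotypes(np.array([[0.0, 1], [0, 2], [0, 0]]))
    with pytest.raises(ValueError, match="monomorphic"):
        ld_r2(g, 0, 1)


@given(st.lists(st.integers(0, 2), min_size=4, max_size=12))
@settings(deadline=None, max_examples=40, derandomize=True)
def test_ld_r2_symmetric_and_coding_invariant(counts):
    x = np.array(counts, dtype=float)
    rng = np.random.default_rng(0)
    y = np.clip(x + rng.integers(-1, 2, size=x.size), 0, 2).astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return
    g = make_genotypes(np.column_stack([x, y, 2 - x]))
    assert ld_r2(g, 0, 1) == pytest.approx(ld_r2(g, 1, 0))
    assert ld_r2(g, 0, 1) == pytest.approx(ld_r2(g, 2, 1))  # swap allele coding


def brute_force_greedy_blocks(r2_matrix, bps, r2_min):
    """Set-based oracle for the bp-ordered greedy all-pairs rule."""
    order = np.argsort(bps, kind="stable")
    assigned = {}
    block = 0
    for pos, seed in enumerate(order):
        if seed in assigned:
            continue
        members = [seed]
        for cand in order[pos + 1:]:
            if cand in assigned:
                continue
            if all(r2_matrix[cand, m] > r2_min for m in members):
                members.append(cand)
        if len(members) > 1:
            block += 1
            for m in members:
                assigned[m] = block
    return assigned


def correlated_toy(seed=4, p=8, n=400):
    rng = np.random.default_rng(seed)
    base = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
    cols = []
    for k in range(p):
        src = base[:, k % 3]
        noise = rng.random(n) < (0.05 + 0.1 * (k % 4))
        col = src.copy()
        col[noise] = rng.binomial(2, 0.4, size=noise.sum())
        cols.append(col)
    return make_genotypes(np.column_stack(cols))


def test_ld_blocks_match_brute_force_oracle_up_to_8_snps():
    g = correlated_toy()
    p = g.n_snps
    r2m = np.ones((p, p))
    for i, j in itertools.combinations(range(p), 2):
        r2m[i, j] = r2m[j, i] = ld_r2(g, i, j)
    for cut in (0.3, 0.5, 0.7):
        got = ld_blocks(g, r2_min=cut)
        expected = brute_force_greedy_blocks(r2m, g.snps["bp"].to_numpy(), cut)
        expected_ids = {g.snp_ids[k]: v for k, v in expected.items()}
        assert got == expected_ids
        # every reported block is a clique at the threshold
        for bl in set(got.values()):
            ids = [s for s, b in got.items() if b == bl]
            idx = [list(g.snp_ids).index(s) for s in ids]
            assert all(
                r2m[a, b] > cut for a, b in itertools.combinations(idx, 2)
            )


def test_ld_blocks_chain_excludes_weak_third():
    # A-B and B-C correlated, A-C weak: the all-pairs rule keeps {A, B}
    rng = np.random.default_rng(9)
    n = 600
    a = rng.binomial(2, 0.5, size=n).astype(float)
    b = a.copy()
    flip = rng.random(n) < 0.06
    b[flip] = rng.binomial(2, 0.5, size=flip.sum())
    c = b.copy()
    flip2 = rng.random(n) < 0.5
    c[flip2] = rng.binomial(2, 0.5, size=flip2.sum())
    g = make_genotypes(np.column_stack([a, b, c]))
    r_ab, r_bc, r_ac = ld_r2(g, 0, 1), ld_r2(g, 1, 2), ld_r2(g, 0, 2)
    assert r_ab > 0.7 and r_ac < 0.7  # construction sanity
    blocks = ld_blocks(g, r2_min=min(0.7, max(r_bc - 0.01, r_ac + 0.01)))
    assert blocks.get("rs0") == blocks.get("rs1") == 1
    assert "rs2" not in blocks


def test_ld_blocks_none_above_threshold():
    rng = np.random.default_rng(12)
    g = make_genotypes(rng.binomial(2, 0.4, size=(300, 5)).astype(float))
    assert ld_blocks(g, r2_min=0.7) == {}
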