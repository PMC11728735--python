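"""Forward simulator: panel genetics, bulk selection, pooled reads, VCF I/O."""

import numpy as np
import pytest

from edscan.synth_data import (
    BulkPair,
    QTLSpec,
    TruthSet,
    select_bulks,
    simulate_panel,
    simulate_pool_reads,
    write_variant_table,
)
from edscan.variant_qc import read_variant_table

CHROMS = {"Chr1": 10_000_000, "Chr2": 10_000_000}
QTL = QTLSpec("Chr1", 5_000_000, additive_effect=1.0, allele_freq=0.5)


def small_panel(h2=0.8, seed=0, n=100, qtls=(QTL,), n_years=2):
    return simulate_panel(n, CHROMS, snp_density=10, qtls=list(qtls), h2=h2,
                          n_years=n_years, seed=seed)


# ---------------------------------------------------------------------------
# simulate_panel
# ---------------------------------------------------------------------------

def test_noise_free_trait_orders_by_qtl_dosage():
    truth = small_panel(h2=1.0)
    dosage = truth.genotypes["Chr1"][:, truth.qtl_snp_index(QTL)]
    pheno = truth.phenotypes[:, 0]
    assert np.array_equal(truth.phenotypes[:, 0], truth.phenotypes[:, 1])
    for d_lo, d_hi in [(0, 1), (1, 2)]:
        if (dosage == d_lo).any() and (dosage == d_hi).any():
            assert pheno[dosage == d_lo].max() < pheno[dosage == d_hi].min() + 1e-12


def test_years_share_genotypes_but_not_noise():
    truth = small_panel(h2=0.5)
    assert truth.phenotypes.shape == (100, 2)
    assert not np.array_equal(truth.phenotypes[:, 0], truth.phenotypes[:, 1])
    again = small_panel(h2=0.5)
    for chrom in CHROMS:
        assert np.array_equal(truth.genotypes[chrom], again.genotypes[chrom])
        assert np.array_equal(truth.snp_positions[chrom], again.snp_positions[chrom])
    assert np.array_equal(truth.phenotypes, again.phenotypes)  # same seed, same noise


def test_snp_positions_sorted_dosages_valid():
    truth = small_panel()
    for chrom, pos in truth.snp_positions.items():
        assert np.all(np.diff(pos) > 0)
        assert set(np.unique(truth.genotypes[chrom])) <= {0, 1, 2}


def test_realized_heritability_near_target():
    """var(g)/var(y) stays in a band around h2=0.5 across seeds."""
    fractions = []
    for seed in range(50):
        truth = simulate_panel(200, {"Chr1": 10_000_000}, 10, [QTL], h2=0.5,
                               n_years=1, seed=seed)
        g = truth.genotypes["Chr1"][:, truth.qtl_snp_index(QTL)].astype(float)
        var_g = np.var(g)  # effect 1.0
        var_y = np.var(truth.phenotypes[:, 0])
        fractions.append(var_g / var_y)
    assert all(0.35 < f < 0.65 for f in fractions)


def test_null_trait_is_pure_noise():
    truth = small_panel(h2=0.0)
    dosage = truth.genotypes["Chr1"][:, truth.qtl_snp_index(QTL)].astype(float)
    assert abs(np.corrcoef(dosage, truth.phenotypes[:, 0])[0, 1]) < 0.35


def test_bad_inputs_rejected():
    with pytest.raises(ValueError, match="non-positive length"):
        simulate_panel(10, {"Chr1": 0}, 10, [], h2=0.5, seed=0)
    with pytest.raises(ValueError, match="outside"):
        simulate_panel(10, {"Chr1": 100}, 10, [QTLSpec("Chr1", 200, 1.0)], h2=0.5, seed=0)
    with pytest.raises(ValueError):
        QTLSpec("Chr1", 10, 1.0, allele_freq=1.0)


# ---------------------------------------------------------------------------
# select_bulks
# ---------------------------------------------------------------------------

def test_tail_selection_order_statistics():
    bulks = select_bulks(list(range(1, 11)), 0.2, 0.2, ids=list(range(1, 11)))
    assert bulks.high_members == {9, 10}
    assert bulks.low_members == {1, 2}


def test_half_tails_partition_even_n():
    bulks = select_bulks([5.0, 1.0, 3.0, 4.0], 0.5, 0.5)
    assert bulks.high_members | bulks.low_members == {0, 1, 2, 3}
    assert not bulks.high_members & bulks.low_members


def test_round_half_up_tail_size(rng):
    values = rng.normal(8, 2, size=85)
    bulks = select_bulks(values, 0.15, 0.15)
    assert len(bulks.high_members) == 13  # round-half-up(0.15 * 85 = 12.75)
    assert len(bulks.low_members) == 13


def test_selection_invariant_to_permutation(rng):
    values = rng.normal(size=40)
    ids = [f"v{i}" for i in range(40)]
    perm = rng.permutation(40)
    a = select_bulks(values, 0.2, 0.2, ids=ids)
    b = select_bulks(values[perm], 0.2, 0.2, ids=[ids[i] for i in perm])
    assert a == b


def test_constant_phenotypes_rejected():
    with pytest.raises(ValueError, match="identical"):
        select_bulks([3.0, 3.0, 3.0, 3.0], 0.2, 0.2)


def test_bulk_pair_validates():
    with pytest.raises(ValueError, match="disjoint"):
        BulkPair(frozenset({1, 2}), frozenset({2, 3}), (0.2, 0.2))
    with pytest.raises(ValueError, match="non-empty"):
        BulkPair(frozenset(), frozenset({1}), (0.2, 0.2))


# ---------------------------------------------------------------------------
# simulate_pool_reads
# ---------------------------------------------------------------------------

def _monomorphic_truth():
    pos = np.array([100, 200, 300], dtype=np.int64)
    return TruthSet(
        chromosome_lengths={"Chr1": 1000},
        snp_positions={"Chr1": pos},
        genotypes={"Chr1": np.zeros((6, 3), dtype=np.int8)},
        phenotypes=np.zeros((6, 1)),
        qtls=[],
        seed=0,
    )


def test_homozygous_ref_panel_yields_no_alt_reads():
    bulks = BulkPair(frozenset({0, 1}), frozenset({2, 3}), (0.3, 0.3))
    sites = simulate_pool_reads(_monomorphic_truth(), bulks, depth=30,
                                error_rate=0.0, seed=1)
    assert all(s.depths[p][1] == 0 for s in sites for p in ("HIGH", "LOW"))


def test_pooled_frequency_converges_at_high_depth():
    truth = small_panel(h2=1.0)
    bulks = select_bulks(truth.phenotypes[:, 0], 0.2, 0.2)
    sites = simulate_pool_reads(truth, bulks, depth=10_000, error_rate=0.0, seed=3)
    members = np.array(sorted(bulks.high_members))
    by_chrom = {c: [s for s in sites if s.chromosome == c] for c in CHROMS}
    for chrom, chrom_sites in by_chrom.items():
        p_true = truth.genotypes[chrom][members].mean(axis=0) / 2
        for s, p in zip(chrom_sites, p_true):
            r, a = s.depths["HIGH"]
            assert abs(a / (r + a) - p) < 0.01 + 3 * np.sqrt(p * (1 - p) / (r + a))


def test_reads_deterministic_under_seed():
    truth = small_panel()
    bulks = select_bulks(truth.phenotypes[:, 0], 0.2, 0.2)
    a = simulate_pool_reads(truth, bulks, depth=40, seed=9)
    b = simulate_pool_reads(truth, bulks, depth=40, seed=9)
    assert [(s.chromosome, s.position, s.depths) for s in a] == [
        (s.chromosome, s.position, s.depths) for s in b
    ]


def test_high_bulk_enriched_for_trait_allele_across_seeds():
    wins = 0
    for seed in range(20):
        truth = small_panel(h2=1.0, seed=seed)
        j = truth.qtl_snp_index(QTL)
        bulks = select_bulks(truth.phenotypes[:, 0], 0.15, 0.15)
        hi = truth.genotypes["Chr1"][np.array(sorted(bulks.high_members)), j].mean()
        lo = truth.genotypes["Chr1"][np.array(sorted(bulks.low_members)), j].mean()
        wins += hi > lo
    assert wins == 20


def test_read_parameter_validation():
    truth = _monomorphic_truth()
    bulks = BulkPair(frozenset({0}), frozenset({1}), (0.2, 0.2))
    with pytest.raises(ValueError):
        simulate_pool_reads(truth, bulks, depth=0)
    with pytest.raises(ValueError):
        simulate_pool_reads(truth, bulks, depth=10, error_rate=0.3)


# ---------------------------------------------------------------------------
# VCF writer
# ---------------------------------------------------------------------------

def test_vcf_round_trip_field_for_field(tmp_path):
    truth = small_panel()
    bulks = select_bulks(truth.phenotypes[:, 0], 0.2, 0.2)
    sites = simulate_pool_reads(truth, bulks, depth=50, seed=5)
    path = tmp_path / "sim.vcf"
    write_variant_table(sites, path, truth.chromosome_lengths)
    back = read_variant_table(path)
    assert len(back) == len(sites)
    for a, b in zip(sites, back):
        assert (a.chromosome, a.position, a.ref_allele, a.alt_allele, a.depths) == (
            b.chromosome, b.position, b.ref_allele, b.alt_allele, b.depths
        )


def test_vcf_writer_rejects_unsorted(tmp_path):
    sites = simulate_pool_reads(
        _monomorphic_truth(),
        BulkPair(frozenset({0}), frozenset({1}), (0.2, 0.2)),
        depth=10, seed=0,
    )
    with pytest.raises(ValueError, match="increasing"):
        write_variant_table(list(reversed(sites)), tmp_path / "bad.vcf")


def test_empty_site_list_gives_header_only_vcf(tmp_path):
    path = tmp_path / "empty.vcf"
    write_variant_table([], path, {"Chr1": 1000})
    assert read_variant_table(path) == []
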