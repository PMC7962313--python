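"""Synthetic genome generator: model construction, emission, dataset assembly."""

import numpy as np
import pytest

import kmersig as ks
from kmersig.io import GenomeRecord, extract_cds
from kmersig.markov import PhasedMarkovModel


def test_group_model_identity_case():
    base = ks.uniform_model(2)
    out = ks.build_group_model(base, base.stationary_gc(), perturbation=0.0)
    np.testing.assert_array_equal(out.probs, base.probs)


def test_group_model_rows_sum_to_one():
    out = ks.build_group_model(ks.uniform_model(2), 0.63, 0.4, seed=3)
    np.testing.assert_allclose(out.probs.sum(axis=2), 1.0, atol=1e-12)


@pytest.mark.parametrize("gc_target,band", [(0.63, (0.61, 0.65)), (0.3, (0.28, 0.32))])
def test_group_model_hits_gc_target_in_simulation(gc_target, band):
    model = ks.build_group_model(ks.uniform_model(2), gc_target, 0.0, seed=1)
    seq, _ = ks.simulate_genome(model, 100_000, seed=2)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert band[0] <= gc <= band[1]


def test_group_model_extreme_gc_limit():
    model = ks.build_group_model(ks.uniform_model(2), 0.99, 0.0, seed=1)
    seq, _ = ks.simulate_genome(model, 5_000, seed=1)
    assert (seq.count("G") + seq.count("C")) / len(seq) > 0.97


@pytest.mark.parametrize("bad_gc", [0.0, 1.0, -0.1, 1.5])
def test_group_model_rejects_bad_gc(bad_gc):
    with pytest.raises(ValueError):
        ks.build_group_model(ks.uniform_model(2), bad_gc, 0.1)


class TestBlend:
    def test_endpoints_exact(self):
        host = ks.build_group_model(ks.uniform_model(2), 0.6, 0.3, seed=1)
        fam = ks.build_group_model(ks.uniform_model(2), 0.4, 0.3, seed=2)
        np.testing.assert_array_equal(ks.blend_models(host, fam, 1.0).probs, host.probs)
        np.testing.assert_array_equal(ks.blend_models(host, fam, 0.0).probs, fam.probs)

    def test_geometric_mixture_hand_case(self):
        # row (0.7,0.1,0.1,0.1) vs (0.1,0.7,0.1,0.1) at w=0.5:
        # sqrt products (sqrt(.07), sqrt(.07), .1, .1) / Z
        host = PhasedMarkovModel(0, np.tile([0.7, 0.1, 0.1, 0.1], (3, 1, 1)))
        fam = PhasedMarkovModel(0, np.tile([0.1, 0.7, 0.1, 0.1], (3, 1, 1)))
        row = ks.blend_models(host, fam, 0.5).probs[0, 0]
        z = 2 * np.sqrt(0.07) + 0.2
        np.testing.assert_allclose(
            row, [np.sqrt(0.07) / z, np.sqrt(0.07) / z, 0.1 / z, 0.1 / z], atol=1e-12
        )

    def test_mismatched_orders_rejected(self):
        with pytest.raises(ValueError):
            ks.blend_models(ks.uniform_model(1), ks.uniform_model(2), 0.5)


class TestSimulateGenome:
    def test_gc_only_model_emits_only_gc(self):
        probs = np.tile([0.0, 0.5, 0.5, 0.0], (3, 1, 1))
        model = PhasedMarkovModel(0, probs)
        seq, _ = ks.simulate_genome(model, 100, seed=0)
        assert set(seq) <= {"G", "C"} and len(seq) == 100

    def test_exact_length_and_cds_contract(self):
        model = ks.uniform_model(2)
        seq, cds = ks.simulate_genome(model, 50_000, seed=4)
        assert len(seq) == 50_000
        covered = sum(e - s + 1 for s, e, _ in cds)
        assert covered >= 0.8 * len(seq)
        assert all((e - s + 1) % 3 == 0 for s, e, _ in cds)

    def test_determinism(self):
        model = ks.uniform_model(2)
        a = ks.simulate_genome(model, 10_000, seed=7)
        b = ks.simulate_genome(model, 10_000, seed=7)
        assert a == b

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ks.simulate_genome(ks.uniform_model(2), 1, seed=0)

    def test_minus_strand_genes_reverse_complemented(self):
        # coding content must survive strand round-trip via extract_cds:
        # a model emitting G-rich phase-0 codon starts should show the same
        # codon bias whether genes are annotated + or -
        model = ks.build_group_model(ks.uniform_model(2), 0.6, 0.3, seed=9)
        seq, cds = ks.simulate_genome(model, 30_000, seed=9, minus_strand_fraction=0.5)
        assert {s for _, _, s in cds} == {"+", "-"}
        rec = GenomeRecord(id="x", sequence=seq, cds=cds)
        cds_seq = extract_cds(rec)
        gc_cds = (cds_seq.count("G") + cds_seq.count("C")) / len(cds_seq)
        assert abs(gc_cds - 0.6) < 0.02


class TestBuildDataset:
    def test_bookkeeping(self):
        spec = ks.SyntheticSpec(
            groups=[
                ks.GroupSpec("O1", "mesophile", 0.4, 0.1, 5),
                ks.GroupSpec("O2", "thermophile", 0.5, 0.1, 5),
                ks.GroupSpec("O3", "hyperthermophile", 0.6, 0.1, 5),
            ],
            mge_families=[
                ks.FamilySpec("f1", "O1", "plasmid", (5_000, 8_000), 0.1, 0.7, 5),
                ks.FamilySpec("f2", "O2", "virus", (5_000, 8_000), 0.1, 0.7, 5),
            ],
            genome_length_range=(10_000, 12_000),
            seed=3,
        )
        ds = ks.build_dataset(spec)
        assert len(ds.sequences) == 25
        assert len(ds.metadata) == 25
        assert list(ds.metadata.columns) == [
            "id", "type", "phylum", "order", "genus", "family",
            "host_order", "niche", "length_bp", "gc",
        ]
        assert (ds.metadata["length_bp"] == ds.metadata["id"].map(
            lambda i: len(ds.sequences[i]))).all()

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = ks.SyntheticSpec(
            groups=[ks.GroupSpec("O1", "mesophile", 0.4, 0.2, 3)],
            genome_length_range=(8_000, 9_000),
            seed=11,
        )
        p1 = ks.build_dataset(spec).write(tmp_path / "a")
        p2 = ks.build_dataset(spec).write(tmp_path / "b")
        assert p1["fasta"].read_bytes() == p2["fasta"].read_bytes()
        assert p1["gff3"].read_bytes() == p2["gff3"].read_bytes()

    def test_duplicate_group_names_rejected(self):
        spec = ks.SyntheticSpec(
            groups=[
                ks.GroupSpec("O1", "mesophile", 0.4, 0.1, 2),
                ks.GroupSpec("O1", "thermophile", 0.5, 0.1, 2),
            ]
        )
        with pytest.raises(ValueError, match="unique"):
            ks.build_dataset(spec)

    def test_planted_transfer_keeps_target_label(self, demo_dataset):
        meta = demo_dataset.metadata.set_index("id")
        assert meta.loc["methano_plasmid_01", "host_order"] == "Methanococcales"


def test_no_signal_groups_show_no_order_effect():
    """Type-I control: with zero signature magnitude and equal GC across
    groups, the PERMANOVA order term should be non-significant in >= 90%
    of seeded replicates."""
    import pandas as pd

    non_sig = 0
    n_rep = 20
    for rep in range(n_rep):
        spec = ks.SyntheticSpec(
            groups=[
                ks.GroupSpec("O1", "mesophile", 0.45, 0.0, 4),
                ks.GroupSpec("O2", "thermophile", 0.45, 0.0, 4),
                ks.GroupSpec("O3", "halophile", 0.45, 0.0, 4),
            ],
            genome_length_range=(10_000, 12_000),
            seed=1000 + rep,
        )
        ds = ks.build_dataset(spec)
        M = ks.profile_matrix(list(ds.sequences.items()), k=5)
        D = ks.euclidean_distance_matrix(M)
        res = ks.permanova_sequential(D, ds.metadata, ["order"], n_perm=499, seed=rep)
        if res.p_value("order") > 0.05:
            non_sig += 1
    # under exact calibration rejections ~ Binomial(20, 0.05); more than 4
    # (the ~99.97% quantile) would indicate spurious group signal
    assert non_sig >= n_rep - 4
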