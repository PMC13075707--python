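"""Gene ordering, sequence building, and the recurrent Cox head."""

import numpy as np
import pytest

from adscca import (GeneAnnotation, OmicsMatrix, SurvivalData,
                    build_sequence, order_genes, predict_risk,
                    train_surv_head)
from adscca.errors import (InsufficientEventsError, InvalidConfigError,
                           ShapeError)
from adscca.survhead import (GeneSequence, SurvHeadConfig, SurvHeadParams,
                             shuffle_test)


def annotation():
    return GeneAnnotation(
        ["g1", "g2", "g3", "g4", "g5"],
        ["chr1", "chr1", "chr2", "chr10", "chrX"],
        np.array([100, 50, 10, 5, 1]),
    )


class TestOrderGenes:
    def test_sorts_by_chromosome_then_start(self):
        out = order_genes(["g1", "g2", "g3"], annotation())
        assert out == ["g2", "g1", "g3"]

    def test_natural_chromosome_order(self):
        # chr2 before chr10, numerals before X
        out = order_genes(["g4", "g3", "g5"], annotation())
        assert out == ["g3", "g4", "g5"]

    def test_unannotated_placed_last_with_warning(self):
        with pytest.warns(UserWarning):
            out = order_genes(["zz", "g1"], annotation())
        assert out == ["g1", "zz"]
        with pytest.raises(InvalidConfigError):
            order_genes(["zz"], annotation(), missing="error")

    def test_total_deterministic_ordering(self):
        genes = ["g5", "g4", "g3", "g2", "g1"]
        once = order_genes(genes, annotation())
        assert order_genes(once, annotation()) == once


class TestBuildSequence:
    def _mats(self):
        x = OmicsMatrix([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"],
                        ["s1", "s2"], "expression")
        y = OmicsMatrix([[5.0, 6.0], [7.0, 8.0]], ["g2", "g3"],
                        ["s1", "s2"], "methylation")
        return x, y

    def test_two_channel_tokens(self):
        x, y = self._mats()
        seq = build_sequence(x, y, ["g1", "g2", "g3"])
        assert seq.tokens.shape == (2, 3, 2)
        assert seq.tokens[0, 1].tolist() == [2.0, 5.0]  # g2 in both

    def test_zero_fill_single_modality(self):
        x, y = self._mats()
        seq = build_sequence(x, y, ["g1", "g3"])
        assert seq.tokens[0, 0].tolist() == [1.0, 0.0]  # g1: expr only
        assert seq.tokens[0, 1].tolist() == [0.0, 6.0]  # g3: meth only

    def test_gene_in_neither_modality(self):
        x, y = self._mats()
        with pytest.raises(InvalidConfigError):
            build_sequence(x, y, ["g9"])


def _training_setup(n=80, L=6, seed=0, censor=0.2):
    rng = np.random.default_rng(seed)
    tokens = rng.normal(size=(n, L, 2))
    coef = rng.choice([-1.0, 1.0], size=L) * 0.6
    lp = tokens[:, :, 0] @ coef
    from adscca import generate_survival
    surv = generate_survival(lp, 1.0, censor, seed=seed + 1,
                             sample_ids=[f"s{i}" for i in range(n)])
    seq = GeneSequence([f"g{l}" for l in range(L)], surv.sample_ids, tokens)
    return seq, surv, lp


class TestSurvHeadTraining:
    def test_zero_epochs_returns_initialization(self):
        seq, surv, _ = _training_setup()
        cfg = SurvHeadConfig(epochs=0, seed=1)
        head = train_surv_head(seq, surv, cfg)
        init = SurvHeadParams(seq.length, cfg)
        assert np.allclose(predict_risk(head, seq), predict_risk(init, seq))

    def test_same_seed_identical_risks(self):
        seq, surv, _ = _training_setup()
        cfg = SurvHeadConfig(epochs=10, seed=2)
        r1 = predict_risk(train_surv_head(seq, surv, cfg), seq)
        r2 = predict_risk(train_surv_head(seq, surv, cfg), seq)
        assert np.allclose(r1, r2, atol=1e-6)

    def test_insufficient_events(self):
        seq, surv, _ = _training_setup(n=10, censor=0.0)
        dead = SurvivalData(surv.sample_ids, surv.time,
                            np.zeros(10, dtype=int))
        with pytest.raises(InsufficientEventsError):
            train_surv_head(seq, dead, SurvHeadConfig(epochs=1))

    def test_learns_risk_ordering_on_train(self):
        from adscca import concordance_index
        seq, surv, _ = _training_setup(n=100, seed=3)
        head = train_surv_head(seq, surv, SurvHeadConfig(epochs=60, seed=4))
        c = concordance_index(predict_risk(head, seq), surv)
        assert c >= 0.48  # at least chance on its own fit; typically ≫

    @pytest.mark.parametrize("pooling", ["mean", "skip-linear"])
    def test_both_pooling_modes_run(self, pooling):
        seq, surv, _ = _training_setup(n=40, L=4)
        cfg = SurvHeadConfig(epochs=3, pooling=pooling, seed=5)
        head = train_surv_head(seq, surv, cfg)
        assert np.isfinite(predict_risk(head, seq)).all()


class TestPredictRisk:
    def test_identical_samples_identical_risks(self):
        seq, surv, _ = _training_setup(n=20, L=4, seed=6)
        tokens = np.repeat(seq.tokens[:1], 5, axis=0)
        dup = GeneSequence(seq.gene_ids, [f"d{i}" for i in range(5)], tokens)
        head = train_surv_head(seq, surv, SurvHeadConfig(epochs=5, seed=7))
        risks = predict_risk(head, dup)
        assert np.allclose(risks, risks[0])

    def test_batch_equals_per_sample(self):
        seq, surv, _ = _training_setup(n=20, L=4, seed=8)
        head = train_surv_head(seq, surv, SurvHeadConfig(epochs=5, seed=9))
        batch = predict_risk(head, seq)
        singles = [predict_risk(head, seq.subset_samples([s]))[0]
                   for s in seq.sample_ids[:4]]
        assert np.allclose(batch[:4], singles, atol=1e-6)

    def test_zero_weights_constant_risk(self):
        seq, _, _ = _training_setup(n=10, L=4, seed=10)
        cfg = SurvHeadConfig(epochs=0, seed=11)
        head = SurvHeadParams(seq.length, cfg)
        for p in head.parameters():
            p.data[:] = 0.0
        risks = predict_risk(head, seq)
        assert np.allclose(risks, risks[0])

    def test_length_mismatch(self):
        seq, surv, _ = _training_setup(n=20, L=4, seed=12)
        head = train_surv_head(seq, surv, SurvHeadConfig(epochs=1, seed=13))
        other = GeneSequence(["a", "b"], seq.sample_ids,
                             np.zeros((20, 2, 2)))
        with pytest.raises(ShapeError):
            predict_risk(head, other)


def test_shuffle_identity_permutation_reproduces_ordered():
    """Forcing the identity permutation must give exactly the ordered
    model's metrics (same seed, same hyperparameters)."""
    rng = np.random.default_rng(14)
    n, L = 60, 5
    x = OmicsMatrix(rng.normal(size=(n, L)), [f"g{l}" for l in range(L)],
                    [f"s{i}" for i in range(n)], "expression")
    y = OmicsMatrix(rng.normal(size=(n, L)), x.gene_ids, x.sample_ids,
                    "methylation")
    from adscca import assign_genomic_coordinates, generate_survival
    ann = assign_genomic_coordinates(x.gene_ids, 1, 5, seed=0)
    lp = x.values @ (rng.choice([-1., 1.], size=L) * 0.5)
    surv = generate_survival(lp, 1.0, 0.2, seed=15, sample_ids=x.sample_ids)
    rep = shuffle_test(x, y, x.gene_ids, ann, surv,
                       SurvHeadConfig(epochs=5, seed=16), n_perm=1, seed=17,
                       permutations=[list(range(L))])
    assert rep.shuffled_cindex[0] == pytest.approx(rep.ordered_cindex)
    assert rep.shuffled_logrank_p[0] == pytest.approx(rep.ordered_logrank_p)
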