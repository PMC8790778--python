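import copy

import numpy as np
import pytest

from dyesol import (
    AuxModel,
    ChempropModel,
    EnsemblePrediction,
    MissingSolventDescriptorError,
    ModelConfig,
    extract_embedding,
    forward_multifidelity,
    forward_single,
    load_descriptor_table,
    predict_ensemble,
    split_by_pair,
    train,
    train_aux,
)
from dyesol.mpnn import EncoderParams


def tiny_config(**kw):
    base = dict(
        dye_encoder=EncoderParams(hidden_size=12, depth=2, seed=0),
        ffn_hidden=16,
        epochs=3,
        batch_size=16,
        ensemble_size=1,
        seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def tiny_dataset(request):
    from dyesol import GeneratorSpec, generate

    spec = GeneratorSpec(
        n_scaffolds=4,
        substituents_per_scaffold=6,
        solvents=(("O", 20.0), ("CCO", 5.0)),
        noise_sd_nm=2.0,
        replicate_fraction=1.0,
        seed=21,
    )
    ds, _ = generate(spec)
    return ds.records


class TestForwardSingle:
    def test_zeroed_output_layer_returns_bias(self):
        model = ChempropModel(tiny_config())
        model.ffn.Ws[-1][...] = 0.0
        model.ffn.bs[-1][...] = 7.5
        a = forward_single(model, "c1ccccc1", "O")
        b = forward_single(model, "Cc1ccc2ccccc2c1", "CCO")
        assert a == b == pytest.approx(7.5)

    def test_inference_determinism(self):
        model = ChempropModel(tiny_config())
        p1 = forward_single(model, "Nc1ccccc1", "O")
        p2 = forward_single(model, "Nc1ccccc1", "O")
        assert p1 == p2

    def test_different_solvents_reach_the_head(self):
        model = ChempropModel(tiny_config())
        a = forward_single(model, "Nc1ccccc1", "O")
        b = forward_single(model, "Nc1ccccc1", "CS(C)=O")
        assert a != b

    def test_descriptor_mode_missing_solvent_raises(self):
        table = load_descriptor_table(None, "cgsd")
        cfg = tiny_config(solvent_mode="cgsd")
        model = ChempropModel(cfg, solvent_table=table)
        with pytest.raises(MissingSolventDescriptorError):
            forward_single(model, "c1ccccc1", "CCCCCCCCCCCC")

    @pytest.mark.parametrize("mode", ["morgan", "cgsd", "minnesota"])
    def test_fixed_solvent_modes_forward(self, mode):
        table = None if mode == "morgan" else load_descriptor_table(None, mode)
        model = ChempropModel(tiny_config(solvent_mode=mode), solvent_table=table)
        out = forward_single(model, "Nc1ccccc1", "O")
        assert np.isfinite(out)


class TestTraining:
    def test_zero_epochs_returns_initialized_model_with_metrics(self, tiny_dataset):
        split = split_by_pair(tiny_dataset, seed=0)
        models, logs = train(tiny_dataset, split, tiny_config(epochs=0))
        assert len(models) == 1
        assert len(logs[0]) == 1 and np.isfinite(logs[0][0]["valid_mae"])

    def test_constant_targets_fit_to_constant(self, tiny_dataset):
        recs = [
            type(r)(r.dye_smiles, r.solvent_smiles, 450.0, r.source, r.low_fidelity_ev, r.row)
            for r in tiny_dataset
        ]
        split = split_by_pair(recs, seed=0)
        models, logs = train(recs, split, tiny_config(epochs=2))
        test = split.indices("test")
        preds = models[0].predict(
            [recs[i].dye_smiles for i in test], [recs[i].solvent_smiles for i in test]
        )
        assert np.allclose(preds, 450.0, atol=5.0)

    def test_fixed_seed_reproduces_training_log(self, tiny_dataset):
        split = split_by_pair(tiny_dataset, seed=1)
        _, logs1 = train(tiny_dataset, split, tiny_config())
        _, logs2 = train(tiny_dataset, split, tiny_config())
        assert logs1 == logs2

    def test_learning_reduces_validation_error(self, tiny_dataset):
        split = split_by_pair(tiny_dataset, seed=2)
        _, logs = train(tiny_dataset, split, tiny_config(epochs=15))
        first, best = logs[0][0]["valid_mae"], min(l["valid_mae"] for l in logs[0])
        assert best < first


class TestMultiFidelity:
    def test_constant_aux_equals_single_with_constant_feature(self, tiny_dataset):
        split = split_by_pair(tiny_dataset, seed=0)
        cfg = tiny_config(n_extra_features=1)
        const = 3.25
        # aux with zeroed output layer -> constant prediction
        aux_cfg = tiny_config(solvent_mode="none", target_units="ev")
        aux_model = ChempropModel(aux_cfg)
        aux_model.ffn.Ws[-1][...] = 0.0
        aux_model.ffn.bs[-1][...] = const
        aux = AuxModel(aux_model)
        m_multi, _ = train(tiny_dataset, split, copy.deepcopy(cfg), aux_model=aux)
        const_feature = np.full(len(tiny_dataset), const)
        m_single, _ = train(
            tiny_dataset, split, copy.deepcopy(cfg), extra_features=const_feature
        )
        test = split.indices("test")
        dyes = [tiny_dataset[i].dye_smiles for i in test]
        solvs = [tiny_dataset[i].solvent_smiles for i in test]
        p_multi = m_multi[0].predict(dyes, solvs, extra=aux.predict_dye(dyes))
        p_single = m_single[0].predict(dyes, solvs, extra=np.full(len(test), const))
        assert np.array_equal(p_multi, p_single)  # bit-for-bit

    def test_aux_scalar_is_solvent_independent(self, tiny_dataset):
        aux, _ = train_aux(tiny_dataset, tiny_config())
        model = ChempropModel(tiny_config(n_extra_features=1))
        dye = tiny_dataset[0].dye_smiles
        a = forward_multifidelity(aux, model, dye, "O")
        b = forward_multifidelity(aux, model, dye, "CCO")
        # identical aux feature; predictions differ only through the solvent
        assert aux.predict_dye([dye])[0] == aux.predict_dye([dye])[0]
        assert a != b

    def test_perfect_low_fidelity_channel_drives_train_mae_down(self, tiny_dataset):
        # targets equal an affine map of the (noiseless) low-fidelity value
        # plus solvent shifts that the extra feature cannot explain; with the
        # true value injected as the extra feature the train MAE collapses
        from dyesol import GeneratorSpec, generate

        spec = GeneratorSpec(
            n_scaffolds=4,
            substituents_per_scaffold=6,
            solvents=(("O", 0.0),),
            noise_sd_nm=0.0,
            lowfi_noise_sd_nm=0.0,
            replicate_fraction=1.0,
            seed=22,
        )
        ds, truth = generate(spec)
        recs = ds.records
        lam_vac = np.array([t["lambda_vacuum_nm"] for t in truth["records"]])
        split = split_by_pair(recs, seed=0)
        models, _ = train(
            recs,
            split,
            tiny_config(epochs=300, max_lr=1e-2),
            extra_features=lam_vac,
        )
        tr = split.indices("train")
        preds = models[0].predict(
            [recs[i].dye_smiles for i in tr],
            [recs[i].solvent_smiles for i in tr],
            extra=lam_vac[tr],
        )
        y = np.array([recs[i].lambda_max_nm for i in tr])
        assert np.mean(np.abs(preds - y)) < 2.0


class TestEnsemble:
    @pytest.mark.parametrize(
        "members,mean,var",
        [([500.0, 500.0, 500.0], 500.0, 0.0), ([499.0, 501.0], 500.0, 1.0)],
    )
    def test_population_statistics(self, members, mean, var):
        p = EnsemblePrediction.from_members(members)
        assert p.mean_nm == mean and p.variance_nm2 == var
        assert p.uncertainty_nm == pytest.approx(np.sqrt(var))

    def test_single_member_flagged(self):
        p = EnsemblePrediction.from_members([500.0])
        assert p.variance_nm2 == 0.0 and not p.uncertainty_available

    def test_predict_ensemble_consistency(self, tiny_dataset):
        split = split_by_pair(tiny_dataset, seed=0)
        models, _ = train(tiny_dataset, split, tiny_config(ensemble_size=2))
        test = split.indices("test")[:4]
        dyes = [tiny_dataset[i].dye_smiles for i in test]
        solvs = [tiny_dataset[i].solvent_smiles for i in test]
        preds = predict_ensemble(models, dyes, solvs)
        for j, p in enumerate(preds):
            members = [m.predict([dyes[j]], [solvs[j]])[0] for m in models]
            assert p.mean_nm == pytest.approx(np.mean(members))
            assert p.variance_nm2 == pytest.approx(np.var(members))


class TestCheckpointing:
    @pytest.mark.parametrize("mode", ["mpnn", "cgsd"])
    def test_round_trip_preserves_predictions(self, tiny_dataset, tmp_path, mode):
        from dyesol.models import load_model, save_model

        table = None if mode == "mpnn" else load_descriptor_table(None, mode)
        split = split_by_pair(tiny_dataset, seed=0)
        models, _ = train(
            tiny_dataset, split, tiny_config(solvent_mode=mode), solvent_table=table
        )
        path = str(tmp_path / "model.npz")
        save_model(models[0], path)
        back = load_model(path)
        dyes = [r.dye_smiles for r in tiny_dataset[:6]]
        solvs = [r.solvent_smiles for r in tiny_dataset[:6]]
        assert np.array_equal(models[0].predict(dyes, solvs), back.predict(dyes, solvs))

    def test_ensemble_round_trip_with_aux(self, tiny_dataset, tmp_path):
        from dyesol.models import load_ensemble, save_ensemble

        split = split_by_pair(tiny_dataset, seed=0)
        aux, _ = train_aux(tiny_dataset, tiny_config())
        models, logs = train(tiny_dataset, split, tiny_config(ensemble_size=2), aux_model=aux)
        run_dir = str(tmp_path / "run")
        save_ensemble(models, run_dir, aux=aux, logs=logs)
        back_models, back_aux = load_ensemble(run_dir)
        dyes = [r.dye_smiles for r in tiny_dataset[:5]]
        solvs = [r.solvent_smiles for r in tiny_dataset[:5]]
        p0 = predict_ensemble(models, dyes, solvs, aux_model=aux)
        p1 = predict_ensemble(back_models, dyes, solvs, aux_model=back_aux)
        assert [p.mean_nm for p in p0] == [p.mean_nm for p in p1]


class TestEmbeddingExtraction:
    def test_spelling_invariance_and_length(self):
        model = ChempropModel(tiny_config())
        e1 = extract_embedding(model, "OCC")
        e2 = extract_embedding(model, "CCO")
        assert np.array_equal(e1, e2)
        assert e1.shape == (12,)

    def test_differs_from_permuted_weight_control(self):
        model = ChempropModel(tiny_config())
        ref = extract_embedding(model, "Nc1ccc2ccccc2c1")
        rng = np.random.default_rng(0)
        control = ChempropModel(tiny_config())
        control.dye_encoder.Wi = rng.permutation(control.dye_encoder.Wi.ravel()).reshape(
            control.dye_encoder.Wi.shape
        )
        alt = extract_embedding(control, "Nc1ccc2ccccc2c1")
        assert not np.allclose(ref, alt)
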