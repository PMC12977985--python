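"""Lesion burden metrics and cognitive standardization."""

import numpy as np
import pandas as pd
import pytest

import avmnet as av
from avmnet.datatypes import CognitiveBattery, DegenerateInputError, RegionalLesionProfile


class TestTotalLesionLoad:
    def test_basic_fraction(self):
        grid = np.zeros((10, 10, 10), dtype=bool)
        grid.ravel()[:50] = True
        assert av.total_lesion_load(grid, 1000) == pytest.approx(0.05)

    def test_empty_mask(self):
        assert av.total_lesion_load(np.zeros((5, 5, 5), dtype=bool), 100) == 0.0

    def test_disjoint_lesions_aggregate(self):
        grid = np.zeros((10, 10, 10), dtype=bool)
        grid[:3, 0, 0] = True  # 3 voxels
        grid.ravel()[-47:] = True  # 47 more, disjoint
        assert av.total_lesion_load(grid, 1000) == pytest.approx(0.05)

    def test_nonpositive_tiv_rejected(self):
        with pytest.raises(ValueError):
            av.total_lesion_load(np.zeros((2, 2, 2), dtype=bool), 0)


class TestRegionalProportion:
    def test_proportions_and_missing_parcel(self, atlas20):
        labels = atlas20.label_volume
        mask = labels == 3  # fully cover parcel 3
        prof = av.regional_lesion_proportion(mask, labels, atlas20)
        assert prof.proportion[2] == 1.0
        assert np.nansum(prof.proportion) == 1.0

    def test_half_parcel_hits_exclusion_boundary(self, atlas20):
        labels = atlas20.label_volume
        vox = np.argwhere(labels == 3)
        mask = np.zeros_like(labels, dtype=bool)
        mask[tuple(vox[: len(vox) // 2].T)] = True
        prof = av.regional_lesion_proportion(mask, labels, atlas20)
        assert prof.proportion[2] == pytest.approx(0.5)
        w = np.ones((20, 20)) - np.eye(20)
        mat = av.ConnectivityMatrix(weights=w, modality="SC")
        masked = av.apply_lesion_mask(mat, prof, cutoff=0.5)
        assert not masked.valid[2]  # >= 50% overlap excludes the node

    def test_background_lesion_all_zero(self, atlas20):
        labels = atlas20.label_volume
        mask = labels == 0
        prof = av.regional_lesion_proportion(mask, labels, atlas20)
        assert np.all(prof.proportion[np.isfinite(prof.proportion)] == 0)
        assert prof.total_lesion_load == 0.0

    def test_voxel_conservation_exact(self, atlas20):
        rng = np.random.default_rng(0)
        labels = atlas20.label_volume
        mask = rng.random(labels.shape) < 0.3
        prof = av.regional_lesion_proportion(mask, labels, atlas20)
        sizes = np.array([(labels == p).sum() for p in atlas20.parcel_ids])
        in_parcels = np.nansum(prof.proportion * sizes)
        background = int((mask & (labels == 0)).sum())
        assert round(in_parcels) + background == int(mask.sum())

    def test_absent_parcel_flagged_nan(self):
        table = pd.DataFrame({
            "parcel_id": [1, 2], "name": ["a", "b"], "hemisphere": ["L", "R"],
            "network": ["DMN", "DMN"], "node_volume": [8, 8]})
        atlas = av.ParcelAtlas(table=table)
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[:2] = 1  # parcel 2 absent
        prof = av.regional_lesion_proportion(np.zeros_like(labels, bool), labels, atlas)
        assert prof.proportion[0] == 0.0
        assert np.isnan(prof.proportion[1])


class TestDmnPredictors:
    @staticmethod
    def _sc(w):
        return av.ConnectivityMatrix(weights=np.asarray(w, float), modality="SC")

    def test_uniform_weights(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            w[i, j] = w[j, i] = 0.7
        assert av.dmn_integrity(self._sc(w), np.array([1, 2, 3])) == pytest.approx(0.7)

    def test_two_edges_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 3.0
        # pairs (1,2)=1, (1,3)=3, (2,3)=0 -> mean 4/3
        assert av.dmn_integrity(self._sc(w), np.array([1, 2, 3])) == pytest.approx(4 / 3)

    def test_excluded_node_drops_its_pairs(self):
        w = np.ones((3, 3)) - np.eye(3)
        mat = self._sc(w)
        mat.valid[2] = False
        assert av.dmn_integrity(mat, np.array([1, 2, 3])) == pytest.approx(1.0)

    def test_too_few_parcels_degenerate(self):
        mat = self._sc(np.zeros((3, 3)))
        mat.valid[1:] = False
        with pytest.raises(DegenerateInputError):
            av.dmn_integrity(mat, np.array([1, 2]))

    def test_attenuation_monotonicity(self, template_sc40, atlas20):
        dmn = np.array([1, 5, 9, 13])
        base = av.dmn_integrity(template_sc40, dmn)
        att = template_sc40.copy()
        idx = dmn - 1
        att.weights[np.ix_(idx, idx)] *= 0.5
        assert av.dmn_integrity(att, dmn) < base

    def test_local_lesion_load(self):
        prof = RegionalLesionProfile(proportion=np.array([0.2, 0.4, 0.9]),
                                     total_lesion_load=0.1)
        assert av.dmn_local_lesion_load(prof, np.array([1, 2])) == pytest.approx(0.3)
        assert av.dmn_local_lesion_load(
            RegionalLesionProfile(proportion=np.zeros(3), total_lesion_load=0.0),
            np.array([1, 2, 3])) == 0.0
        with pytest.raises(ValueError):
            av.dmn_local_lesion_load(prof, np.array([], dtype=int))


def make_battery(scores: pd.DataFrame) -> CognitiveBattery:
    flags = {"MMSE": False, "MoCA": False, "RT": True}
    return CognitiveBattery(scores=scores, latency_flags=flags,
                            domain_map={"Global": ("MMSE", "MoCA"),
                                        "Attention/Speed": ("RT",)})


class TestZscoreBattery:
    @pytest.fixture
    def battery(self, rng):
        controls = pd.DataFrame({
            "MMSE": rng.normal(27, 2, 30), "MoCA": rng.normal(26, 2, 30),
            "RT": rng.normal(60, 10, 30)},
            index=[f"NC{i}" for i in range(30)])
        patients = pd.DataFrame({"MMSE": [27.0], "MoCA": [26.0], "RT": [70.0]},
                                index=["P1"])
        return make_battery(pd.concat([controls, patients]))

    def test_control_group_mean_zero_sd_one(self, battery):
        ctrl_ids = [i for i in battery.scores.index if i.startswith("NC")]
        domains = av.zscore_battery(battery, ctrl_ids)
        for col in ("Global",):
            vals = domains.loc[ctrl_ids, col]
            # domain = mean of two unit-variance z-scores, so mean is 0
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)

    def test_latency_inversion(self, battery):
        ctrl_ids = [i for i in battery.scores.index if i.startswith("NC")]
        mu = battery.scores.loc[ctrl_ids, "RT"].mean()
        sd = battery.scores.loc[ctrl_ids, "RT"].std(ddof=1)
        domains = av.zscore_battery(battery, ctrl_ids)
        expected = -(70.0 - mu) / sd  # one SD slower -> about -1 after inversion
        assert domains.loc["P1", "Attention/Speed"] == pytest.approx(expected)
        assert expected < 0

    def test_domain_mean_of_balanced_z(self):
        scores = pd.DataFrame({"MMSE": [27, 29, 25], "MoCA": [26, 24, 28],
                               "RT": [60, 61, 59]},
                              index=["a", "b", "c"], dtype=float)
        domains = av.zscore_battery(make_battery(scores), ["a", "b", "c"])
        # subject b: MMSE z = +1, MoCA z = -1 -> Global 0
        assert domains.loc["b", "Global"] == pytest.approx(0.0)

    def test_zero_control_sd_names_test(self):
        scores = pd.DataFrame({"MMSE": [27, 27], "MoCA": [26, 25], "RT": [60, 61]},
                              index=["a", "b"], dtype=float)
        with pytest.raises(ValueError, match="MMSE"):
            av.zscore_battery(make_battery(scores), ["a", "b"])


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 80
        cov = pd.DataFrame({"age": rng.uniform(20, 70, n),
                            "sex": rng.choice(["M", "F"], n),
                            "education": rng.uniform(6, 20, n)})
        scores = pd.DataFrame({"Global": 2 * cov["age"] + rng.normal(0, 1, n)})
        out = av.residualize(scores, cov)
        r = np.corrcoef(out["Global"], cov["age"])[0, 1]
        assert abs(r) < 1e-10
        assert out["Global"].std(ddof=1) == pytest.approx(1.0)

    def test_exact_linear_function_errors(self, rng):
        n = 30
        cov = pd.DataFrame({"age": rng.uniform(20, 70, n)})
        scores = pd.DataFrame({"Global": 2 * cov["age"] + 1})
        with pytest.raises(ValueError, match="zero variance"):
            av.residualize(scores, cov)

    def test_collinear_design_errors(self, rng):
        n = 30
        age = rng.uniform(20, 70, n)
        cov = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(ValueError, match="rank-deficient"):
            av.residualize(pd.DataFrame({"s": rng.normal(size=n)}), cov)
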