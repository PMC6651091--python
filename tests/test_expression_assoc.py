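import numpy as np
import pandas as pd
import pytest

from methylcontext.expression_assoc import (
    kde,
    position_expression_report,
    select_extremes,
    silverman_bandwidth,
    t_score,
)
from methylcontext.gene_context import GeneFeatureAnnotation


def two_pass_oracle(values):
    """Independent per-row standardisation: explicit two-pass mean/SD loops."""
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        row = values[i]
        mean = sum(row) / len(row)
        var = sum((x - mean) ** 2 for x in row) / (len(row) - 1)
        out[i] = (row - mean) / np.sqrt(var)
    return out


class TestTScore:
    def test_hand_computed_example(self):
        t = t_score(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")))
        assert np.allclose(t.values, [[-1.0, 0.0, 1.0]])

    def test_constant_gene_flagged_nan(self):
        t = t_score(pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc")))
        assert t.isna().all().all()

    def test_matches_two_pass_oracle(self, rng):
        values = rng.normal(10, 3, size=(50, 6))
        t = t_score(pd.DataFrame(values))
        assert np.allclose(t.values, two_pass_oracle(values), atol=1e-12)

    def test_requires_two_animals(self):
        with pytest.raises(ValueError):
            t_score(pd.DataFrame([[1.0]], columns=["a"]))


class TestSelectExtremes:
    GROUPS = {f"MHF_{i}": "MHF" for i in range(14)}
    GROUPS.update({f"PHF_{i}": "PHF" for i in range(13)})
    GROUPS.update({f"CON_{i}": "CON" for i in range(13)})

    def _matrix(self, rng, n_genes=20):
        cols = list(self.GROUPS)
        return pd.DataFrame(
            rng.normal(0, 1, size=(n_genes, len(cols))),
            index=[f"g{i}" for i in range(n_genes)],
            columns=cols,
        )

    def test_no_extremes_below_threshold(self, rng):
        values = self._matrix(rng)
        sel = select_extremes(t_score(values), self.GROUPS, k_sd=4)
        assert sel.entries.empty and sel.gene_groups == {}

    def test_planted_outliers_selected_exactly(self, rng):
        """One 12-SD outlier per gene (40 animals) is the only entry passing
        the 4-SD per-gene threshold, and labels the gene by its group."""
        values = self._matrix(rng)
        planted = {}
        for i, gene in enumerate(values.index):
            col = values.columns[i % len(values.columns)]
            values.loc[gene, col] += 12.0
            planted[gene] = col
        sel = select_extremes(t_score(values), self.GROUPS, k_sd=4)
        got = dict(zip(sel.entries["gene"], sel.entries["animal"]))
        assert got == planted
        for gene, col in planted.items():
            group = self.GROUPS[col]
            if group in ("MHF", "PHF"):
                assert sel.gene_groups[gene] == f"higher_in_{group}"
            else:
                assert gene not in sel.gene_groups  # CON extremes set no contrast label

    def test_low_extreme_labels_opposite_group(self, rng):
        values = self._matrix(rng)
        values.loc["g0", "MHF_0"] -= 12.0
        sel = select_extremes(t_score(values), self.GROUPS, k_sd=4)
        assert sel.gene_groups["g0"] == "higher_in_PHF"

    def test_conflicting_extremes_excluded(self, rng):
        values = self._matrix(rng)
        values.loc["g0", "MHF_0"] += 30.0
        values.loc["g0", "PHF_0"] += 30.0
        sel = select_extremes(t_score(values), self.GROUPS, k_sd=4)
        assert "g0" in sel.excluded_conflicts
        assert "g0" not in sel.gene_groups

    def test_selection_invariant_under_per_gene_affine_rescaling(self, rng):
        values = self._matrix(rng)
        values.loc["g3", "PHF_2"] += 15.0
        scaled = values.mul(rng.uniform(0.5, 20.0, size=len(values)), axis=0)
        scaled = scaled.add(rng.normal(0, 100.0, size=len(values)), axis=0)
        a = select_extremes(t_score(values), self.GROUPS, k_sd=4)
        b = select_extremes(t_score(scaled), self.GROUPS, k_sd=4)
        assert a.gene_groups == b.gene_groups
        assert list(a.entries["gene"]) == list(b.entries["gene"])


class TestKde:
    def test_single_position_peaks_there(self):
        curve = kde([50.0], bandwidth=3.0)
        assert curve.grid[np.argmax(curve.density)] == pytest.approx(50.0, abs=0.2)
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_positions_give_symmetric_curve(self):
        curve = kde([30.0, 70.0, 45.0, 55.0], bandwidth=5.0)
        assert np.allclose(curve.density, curve.density[::-1], atol=1e-9)

    def test_integral_one_even_with_boundary_mass(self, rng):
        positions = np.concatenate([rng.uniform(0, 5, 30), rng.uniform(90, 100, 30)])
        curve = kde(positions)
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)
        assert (curve.density >= 0).all()

    def test_matches_direct_sum_of_kernels_formula(self, rng):
        """Spot-check the estimate against an independently coded reflected
        Gaussian mixture at 10 grid points."""
        positions = rng.uniform(0, 100, size=100)
        h = 4.0
        curve = kde(positions, bandwidth=h)
        idx = np.linspace(0, len(curve.grid) - 1, 10).astype(int)
        for i in idx:
            x = curve.grid[i]
            total = 0.0
            for p in positions:
                for c in (p, -p, 200.0 - p):
                    total += np.exp(-0.5 * ((x - c) / h) ** 2)
            expected = total / (len(positions) * h * np.sqrt(2 * np.pi))
            assert curve.density[i] == pytest.approx(expected, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kde([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kde([101.0])

    def test_silverman_fallback_for_degenerate_spread(self):
        assert silverman_bandwidth(np.array([42.0])) == 5.0
        assert silverman_bandwidth(np.array([42.0, 42.0, 42.0])) == 5.0


def _annotation(gene_id, position):
    return GeneFeatureAnnotation(gene_id, "gene_body", "intron", position)


class TestPositionExpressionReport:
    def _selection(self, gene_groups):
        from methylcontext.expression_assoc import ExtremeSelection

        return ExtremeSelection(pd.DataFrame(), gene_groups, [])

    def test_planted_downstream_stratum_mass(self, rng):
        """PHF-higher methylation planted only past position 60 in PHF-high
        genes concentrates that stratum's density above 60."""
        positions = rng.uniform(62, 98, size=40)
        annotations = [_annotation(f"g{i}", p) for i, p in enumerate(positions)]
        directions = ["PHF_higher"] * len(annotations)
        selection = self._selection({f"g{i}": "higher_in_PHF" for i in range(len(annotations))})
        curves, corr, _ = position_expression_report(annotations, directions, selection)
        (curve,) = curves
        assert curve.stratum == ("higher_in_PHF", "PHF_higher")
        mask = curve.grid > 60
        mass = np.trapezoid(curve.density[mask], curve.grid[mask])
        assert mass > 0.8

    def test_identical_position_sets_give_identical_curves(self):
        positions = [20.0, 40.0, 80.0]
        ann_a = [_annotation(f"a{i}", p) for i, p in enumerate(positions)]
        ann_b = [_annotation(f"b{i}", p) for i, p in enumerate(positions)]
        sel = self._selection(
            {a.gene_id: "higher_in_MHF" for a in ann_a}
            | {b.gene_id: "higher_in_PHF" for b in ann_b}
        )
        curves, _, _ = position_expression_report(
            ann_a + ann_b, ["MHF_higher"] * 3 + ["MHF_higher"] * 3, sel
        )
        assert len(curves) == 2
        assert np.allclose(curves[0].density, curves[1].density)

    def test_no_extreme_genes_gives_empty_report(self):
        curves, corr, _ = position_expression_report(
            [_annotation("g", 50.0)], ["MHF_higher"], self._selection({})
        )
        assert curves == [] and corr.empty

    def test_promoter_dmrs_excluded_and_counted(self):
        anns = [
            GeneFeatureAnnotation("g0", "promoter"),
            _annotation("g1", 30.0),
        ]
        sel = self._selection({"g0": "higher_in_MHF", "g1": "higher_in_MHF"})
        curves, _, n_prom = position_expression_report(anns, ["MHF_higher"] * 2, sel)
        assert n_prom == 1
        assert len(curves) == 1


class TestSignRecovery:
    def test_position_effect_sign_recovered_from_simulation(self):
        """End-to-end over the generator: downstream PHF-higher DMRs raise PHF
        expression, and the recovered position/direction association in the
        PHF-high stratum is concentrated downstream. Selection runs at 2 SD:
        a per-gene z-score over n animals is bounded by (n-1)/sqrt(n), so the
        12-animal design cannot reach 4."""
        from methylcontext.formats_io import GeneModel, GenomicInterval
        from methylcontext.synthetic_data import SimulationConfig, simulate_expression

        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_samples_per_group=4, expression_effect=3.0,
                expression_noise_sd=0.3, planted_dmr_count=0, seed=100 + seed,
            )
            genes = [
                GeneModel(f"g{i}", GenomicInterval("c", 1000 + 10_000 * i, 6000 + 10_000 * i, "+"),
                          (GenomicInterval("c", 1000 + 10_000 * i, 6000 + 10_000 * i, "+"),))
                for i in range(40)
            ]
            positions = np.where(np.arange(40) % 2, 90.0, 10.0)
            links = pd.DataFrame(
                {"gene_id": [g.gene_id for g in genes],
                 "direction": "PHF_higher",
                 "relative_position": positions}
            )
            expr = simulate_expression(genes, links, cfg)
            scores = t_score(expr)
            sel = select_extremes(scores, cfg.group_of, k_sd=2.0)
            # genes with downstream DMRs should surface as PHF-high, genes
            # with TSS-proximal DMRs as MHF-high (PHF repressed)
            correct = wrong = 0
            for gene, label in sel.gene_groups.items():
                rel = positions[int(gene[1:])]
                expected = "higher_in_PHF" if rel > 50 else "higher_in_MHF"
                if label == expected:
                    correct += 1
                else:
                    wrong += 1
            if correct + wrong > 0 and correct / (correct + wrong) >= 0.95:
                hits += 1
        assert hits >= 9  # sign recovered in >= 95% of runs (allow one MC miss)
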