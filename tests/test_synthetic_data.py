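"""Synthetic-data generator: determinism, planted structure, round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from mircascade.expression import percentile_shift_normalize
from mircascade.promoter_motif import PromoterSet, read_jaspar, read_promoters_fasta, scan_promoter
from mircascade.mirna_rank import read_target_tables
from mircascade.synthetic_data import (
    SimConfig,
    generate_dataset,
    generate_expression,
    generate_target_tables,
    plant_motifs,
    write_dataset,
)
from mircascade.expression import read_expression

from tests.test_promoter_motif import UNIFORM, degenerate_pwm

SMALL = dict(n_genes=120, n_go_terms=10, promoter_length=200, n_pwms=4,
             n_planted_pwms=2, n_mirnas=8)


class TestGenerateDataset:
    def test_seed_determinism(self):
        a = generate_dataset(SimConfig(**SMALL, seed=7))
        b = generate_dataset(SimConfig(**SMALL, seed=7))
        c = generate_dataset(SimConfig(**SMALL, seed=8))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        assert a.promoters.sequences == b.promoters.sequences
        assert [t.targets for t in a.target_tables] == [t.targets for t in b.target_tables]
        assert not a.expression.values.equals(c.expression.values)

    def test_planted_count_arithmetic(self):
        _, truth = generate_expression(SimConfig(n_genes=1000, frac_strain_de=0.05))
        assert len(truth.strain_de) == 50

    def test_null_config_all_identical_values(self):
        config = SimConfig(**SMALL, frac_strain_de=0.0, frac_lps_de=0.0,
                           noise_sd_log2=0.0)
        expr, truth = generate_expression(config)
        vals = expr.values.to_numpy()
        assert np.allclose(vals, vals[:, [0]])
        assert truth.strain_de == {} and truth.lps_de == {}

    def test_planted_effects_realized_in_log2_means(self):
        config = SimConfig(**SMALL, seed=5)
        expr, truth = generate_expression(config)
        log2 = np.log2(expr.values)
        first = expr.samples_where(strain=config.strains[0])
        second = expr.samples_where(strain=config.strains[1])
        for gene, effect in truth.strain_de.items():
            diff = log2.loc[gene, first].mean() - log2.loc[gene, second].mean()
            assert diff == pytest.approx(effect, abs=4 * config.noise_sd_log2)

    def test_effect_realization_tolerance_over_seeds(self):
        # empirical mean log2 difference within 3*sd/sqrt(r*conditions) for
        # >= 95% of planted genes pooled over 100 seeds
        config = SimConfig(n_genes=60, frac_strain_de=0.2, n_go_terms=5,
                           promoter_length=100, n_pwms=2, n_planted_pwms=1,
                           n_mirnas=4)
        r_cond = config.n_replicates_per_condition * len(config.treatments) * len(
            config.durations
        )
        tol = 3 * config.noise_sd_log2 / math.sqrt(r_cond)
        ok = total = 0
        for seed in range(100):
            cfg = SimConfig(**{**config.__dict__, "seed": seed})
            expr, truth = generate_expression(cfg)
            log2 = np.log2(expr.values)
            first = expr.samples_where(strain=cfg.strains[0])
            second = expr.samples_where(strain=cfg.strains[1])
            diffs = (
                log2.loc[list(truth.strain_de), first].mean(axis=1)
                - log2.loc[list(truth.strain_de), second].mean(axis=1)
            )
            # SD of the between-strain mean difference is sd*sqrt(2/(r*cond));
            # the declared tolerance 3*sd/sqrt(r*cond) is ~2.1 of those SDs
            for gene, diff in diffs.items():
                total += 1
                ok += abs(diff - truth.strain_de[gene]) <= tol
        assert ok / total >= 0.95

    def test_flags_threshold_raw_intensity(self):
        config = SimConfig(**SMALL, flag_absent_quantile=0.2, seed=3)
        expr, _ = generate_expression(config)
        raw = expr.values.to_numpy()
        flags = expr.flags.to_numpy()
        thresh = np.quantile(raw, 0.2, axis=0)
        assert ((flags == "A") == (raw < 0.98 * thresh[None, :])).all()

    def test_cross_references(self):
        ds = generate_dataset(SimConfig(**SMALL, seed=9))
        genes = set(ds.expression.gene_ids)
        assert set(ds.truth.strain_de) <= genes
        assert set(ds.promoters.sequences) == genes
        pwm_ids = {p.id for p in ds.pwms}
        assert set(ds.truth.planted_pwms) <= pwm_ids
        planted_mirna = ds.truth.mirna_truth[0]
        for table in ds.target_tables:
            assert planted_mirna in table.targets
        assert ds.truth.tf_set <= genes

    def test_contradictory_fractions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SimConfig(frac_strain_de=0.7, frac_lps_de=0.6).validate()

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            SimConfig(n_replicates_per_condition=1).validate()

    def test_motif_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError, match="longer than promoter"):
            SimConfig(promoter_length=6, pwm_length_range=(8, 10)).validate()


class TestPlantMotifs:
    @pytest.fixture()
    def promoters(self):
        rng = np.random.default_rng(0)
        return PromoterSet(
            {f"g{i}": "".join(rng.choice(list("ACGT"), 100)) for i in range(10)}
        )

    def test_rate_zero_is_identity(self, promoters):
        pwm = degenerate_pwm("ACGT")
        out, ins = plant_motifs(promoters, pwm, set(promoters.sequences), 0.0, 1)
        assert out.sequences == promoters.sequences
        assert ins == []

    def test_degenerate_acgt_planted_at_recorded_positions(self, promoters):
        pwm = degenerate_pwm("ACGT")
        out, ins = plant_motifs(promoters, pwm, set(promoters.sequences), 1.0, 2)
        assert len(ins) == 10
        for rec in ins:
            written = out.sequences[rec.gene][rec.position : rec.position + 4]
            expected = "ACGT" if rec.strand == "+" else "ACGT".translate(
                str.maketrans("ACGT", "TGCA")
            )[::-1]
            assert written == expected

    def test_half_rate_plants_five_and_scan_recovers(self, promoters):
        site = "ACGTACGTCC"  # long enough to not occur by chance in 100 bp
        pwm = degenerate_pwm(site)
        out, ins = plant_motifs(promoters, pwm, set(promoters.sequences), 0.5, 3)
        assert len(ins) == 5
        modified = {r.gene for r in ins}
        for rec in ins:
            hits = scan_promoter(out.sequences[rec.gene], pwm, UNIFORM, 1.0)
            assert any(h.position == rec.position for h in hits)
        for g in set(promoters.sequences) - modified:
            assert out.sequences[g] == promoters.sequences[g]

    def test_missing_gene_rejected(self, promoters):
        with pytest.raises(ValueError, match="without promoters"):
            plant_motifs(promoters, degenerate_pwm("ACGT"), {"nope"}, 1.0, 0)

    def test_motif_longer_than_promoter_rejected(self):
        proms = PromoterSet({"g": "ACGTA"})
        with pytest.raises(ValueError, match="longer than promoter"):
            plant_motifs(proms, degenerate_pwm("ACGTACGT"), {"g"}, 1.0, 0)


class TestTargetTables:
    def _truth(self, n_tfs=5):
        from mircascade.synthetic_data import SyntheticTruth

        tfs = tuple(f"TF{i}" for i in range(n_tfs))
        return SyntheticTruth(
            strain_de={}, lps_de={}, cluster_assignment={}, planted_terms={},
            planted_pwms={}, pwm_tf_map={}, mirna_truth=("miR-true", tfs),
        )

    def test_coverage_ceiling_arithmetic(self):
        truth = self._truth(5)
        universe = [f"g{i}" for i in range(50)] + [f"TF{i}" for i in range(5)]
        tables = generate_target_tables(truth, ["miR-true", "m2"], 0.8, 0.0,
                                        universe, seed=1)
        for t in tables:
            assert len(t.targets["miR-true"]) == 4  # ceil(0.8 * 5)
        total = sum(len(t.targets["miR-true"]) for t in tables)
        assert total == 8

    def test_full_coverage_no_decoys_unique_nonzero(self):
        truth = self._truth(4)
        universe = [f"TF{i}" for i in range(4)] + [f"g{i}" for i in range(20)]
        tables = generate_target_tables(truth, ["miR-true", "d1", "d2"], 1.0, 0.0,
                                        universe, seed=2)
        tf_set = set(truth.mirna_truth[1])
        for t in tables:
            counts = {m: len(g & tf_set) for m, g in t.targets.items()}
            assert counts["miR-true"] == 4
            assert counts["d1"] == counts["d2"] == 0

    def test_empty_mirna_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_target_tables(self._truth(), [], 0.5, 0.1, ["g1"], 0)


class TestWriteDataset:
    def test_files_round_trip(self, tmp_path):
        ds = generate_dataset(SimConfig(**SMALL, seed=4))
        paths = write_dataset(ds, tmp_path)
        back = read_expression(paths["expression"], paths["samples"], paths["flags"])
        np.testing.assert_allclose(
            back.values.to_numpy(), ds.expression.values.to_numpy(), rtol=1e-9
        )
        assert (back.flags.to_numpy() == ds.expression.flags.to_numpy()).all()
        proms = read_promoters_fasta(paths["promoters"])
        assert proms.sequences == ds.promoters.sequences
        pwms = read_jaspar(paths["pwms"])
        assert [p.id for p in pwms] == [p.id for p in ds.pwms]
        tables = read_target_tables(paths["targets"])
        got = {t.algorithm: {m: g for m, g in t.targets.items() if g} for t in tables}
        want = {t.algorithm: {m: g for m, g in t.targets.items() if g}
                for t in ds.target_tables}
        assert got == want

    def test_normalization_of_written_matrix(self, tmp_path):
        ds = generate_dataset(SimConfig(**SMALL, seed=6))
        paths = write_dataset(ds, tmp_path)
        back = read_expression(paths["expression"], paths["samples"], paths["flags"])
        norm, _ = percentile_shift_normalize(back)
        assert norm.scale == "log2"
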