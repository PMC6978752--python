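"""Synthetic-data generators: exact ground truth and reproducibility."""

import numpy as np
import pytest

from seedtrace import (
    DivergenceSpec,
    OrthologPair,
    PlantSpec,
    Region,
    annotate_pair,
    find_sites,
    generate_assay_tables,
    generate_ortholog,
    generate_transcript,
    let7_query,
    mean_clinical_score,
    rlu,
)
from seedtrace.assay_quant import quantify_qpcr, quantify_transwell


class TestGenerateTranscript:
    def test_planted_site_recovered_at_exact_coordinates(self, let7):
        record, truth = generate_transcript(
            length=500,
            plants=[PlantSpec(Region.UTR3, 10, 10, 0)],
            rng_seed=11,
        )
        found = find_sites(record, let7)
        assert len(found) == len(truth) == 1
        assert found[0].same_locus(truth[0])
        assert found[0].region is Region.UTR3

    def test_plants_in_all_regions(self, let7):
        plants = [
            PlantSpec(Region.UTR5, 5, 8, 1),
            PlantSpec(Region.CDS, 40, 10, 0),
            PlantSpec(Region.UTR3, 20, 6, 4),
        ]
        record, truth = generate_transcript(length=600, plants=plants, rng_seed=7)
        found = find_sites(record, let7)
        assert [(s.start, s.end, s.seed_offset) for s in found] == [
            (t.start, t.end, t.seed_offset) for t in truth
        ]
        assert [s.region for s in found] == [Region.UTR5, Region.CDS, Region.UTR3]

    def test_seed_free_background_has_zero_sites(self, let7):
        for seed_val in range(10):
            record, truth = generate_transcript(length=800, rng_seed=seed_val)
            assert truth == []
            assert find_sites(record, let7) == []

    def test_bit_reproducible(self):
        a, _ = generate_transcript(400, plants=[PlantSpec(Region.CDS, 3, 7, 2)], rng_seed=5)
        b, _ = generate_transcript(400, plants=[PlantSpec(Region.CDS, 3, 7, 2)], rng_seed=5)
        assert a.sequence == b.sequence

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError):
            generate_transcript(
                100, plants=[PlantSpec(Region.UTR5, 0, 10, 0)], cds_start=4, cds_end=90
            )
        with pytest.raises(ValueError):  # blocks closer than k
            generate_transcript(
                500,
                plants=[PlantSpec(Region.CDS, 0, 10, 0), PlantSpec(Region.CDS, 12, 10, 0)],
            )

    def test_gc_fraction_is_respected(self):
        record, _ = generate_transcript(4000, gc_fraction=0.7, rng_seed=3)
        gc = sum(c in "GC" for c in record.sequence) / len(record.sequence)
        assert gc == pytest.approx(0.7, abs=0.03)


class TestGenerateOrtholog:
    def _base(self, rng_seed=1):
        return generate_transcript(
            length=400,
            plants=[PlantSpec(Region.CDS, 30, 10, 0), PlantSpec(Region.UTR3, 15, 7, 3)],
            rng_seed=rng_seed,
        )

    def test_zero_divergence_is_identity(self, let7):
        record, truth = self._base()
        orth, surviving = generate_ortholog(record, truth, DivergenceSpec(0.0))
        assert orth.sequence == record.sequence
        assert [(s.start, s.end, s.match_len, s.seed_offset) for s in surviving] == [
            (t.start, t.end, t.match_len, t.seed_offset) for t in truth
        ]

    def test_preserved_sites_survive_any_divergence(self, let7):
        record, truth = self._base()
        spec = DivergenceSpec(0.2, indel_rate=0.02, site_policy="preserve", rng_seed=9)
        orth, surviving = generate_ortholog(record, truth, spec)
        assert len(surviving) == len(truth)
        for site in surviving:
            block = orth.sequence[site.start : site.end]
            assert block == let7.extended_seed[
                site.seed_offset : site.seed_offset + site.match_len
            ]

    def test_ablation_removes_every_planted_site(self, let7):
        record, truth = self._base()
        spec = DivergenceSpec(0.0, site_policy="ablate", rng_seed=2)
        orth, surviving = generate_ortholog(record, truth, spec)
        assert surviving == []
        found = find_sites(orth, let7)
        truth_intervals = {(t.start, t.end) for t in truth}
        assert all((s.start, s.end) not in truth_intervals for s in found)

    def test_exposed_site_survival_is_nested_across_rates(self):
        # threshold-coupled substitutions: raising the rate at a fixed seed
        # only adds edits, so the surviving-site set can only shrink
        record, truth = self._base()
        survivors = []
        for rate in (0.0, 0.02, 0.05, 0.1, 0.2, 0.5):
            spec = DivergenceSpec(rate, site_policy="expose", rng_seed=33)
            _, surviving = generate_ortholog(record, truth, spec)
            survivors.append({(s.match_len, s.seed_offset) for s in surviving})
        counts = [len(s) for s in survivors]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == len(truth)

    def test_bit_reproducible(self):
        record, truth = self._base()
        spec = DivergenceSpec(0.1, indel_rate=0.02, rng_seed=4)
        a, _ = generate_ortholog(record, truth, spec)
        b, _ = generate_ortholog(record, truth, spec)
        assert a.sequence == b.sequence

    def test_moderate_divergence_pairs_mostly_called_conserved(self, let7):
        conserved = total = 0
        for i in range(40):
            record, truth = generate_transcript(
                length=300,
                plants=[PlantSpec(Region.CDS, 20, 10, 0)],
                rng_seed=100 + i,
            )
            spec = DivergenceSpec(0.05, indel_rate=0.01, rng_seed=200 + i)
            orth, surviving = generate_ortholog(record, truth, spec)
            pair = OrthologPair(record, orth, record.gene_symbol)
            sites_a, _, _ = annotate_pair(pair, let7)
            total += len(truth)
            conserved += sum(bool(s.conserved) for s in sites_a
                             if any(s.start == t.start for t in truth))
        assert total == 40
        assert conserved / total >= 0.95

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DivergenceSpec(-0.1)
        with pytest.raises(ValueError):
            DivergenceSpec(0.1, mean_indel_len=0.5)
        with pytest.raises(ValueError):
            DivergenceSpec(0.1, site_policy="maybe")


class TestGenerateAssayTables:
    def test_zero_noise_recovers_truth_exactly(self):
        tables = generate_assay_tables(rng_seed=0, noise=False)
        truth = tables["truth"]
        luc = tables["luciferase"]
        for label, expected in truth["rlu"].items():
            rows = luc[luc["group_label"] == label]
            for f, r in zip(rows["firefly"], rows["renilla"]):
                assert rlu(f, r) == pytest.approx(expected)
        tw = quantify_transwell(tables["transwell"]).set_index(
            ["group_label", "condition"]
        )
        for key, expected in truth["percent_migration"].items():
            group, condition = key.split(":")
            assert tw.loc[(group, condition), "mean"] == pytest.approx(expected)
        qp = quantify_qpcr(tables["qpcr"]).set_index(["group_label", "gene"])
        for key, expected in truth["fold_expression"].items():
            group, gene = key.split(":")
            assert qp.loc[(group, gene), "mean"] == pytest.approx(expected)

    def test_noisy_rlu_recovers_true_ratio_within_tolerance(self):
        tables = generate_assay_tables(rng_seed=1, noise=True)
        truth = tables["truth"]["rlu"]
        luc = tables["luciferase"]
        for label, expected in truth.items():
            rows = luc[luc["group_label"] == label]
            ratios = np.log([rlu(f, r) for f, r in zip(rows["firefly"], rows["renilla"])])
            # lognormal ratio noise: both channels sigma=0.1 -> ratio sigma ~ 0.1*sqrt(2)
            sem = 0.1 * np.sqrt(2) / np.sqrt(len(ratios))
            assert abs(ratios.mean() - np.log(expected)) < 4 * sem

    def test_clinical_scores_on_scale_and_summarizable(self):
        tables = generate_assay_tables(rng_seed=2)
        clin = tables["clinical_score"]
        assert set(clin["score"]) <= set(range(6))
        curve = mean_clinical_score(clin[clin["group_label"] == "WT"])
        assert curve["mean_score"].max() > curve.loc[0, "mean_score"]

    def test_bit_reproducible(self):
        a = generate_assay_tables(rng_seed=3)
        b = generate_assay_tables(rng_seed=3)
        for kind in ("luciferase", "transwell", "qpcr", "clinical_score"):
            assert a[kind].equals(b[kind])
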