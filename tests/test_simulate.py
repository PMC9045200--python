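"""Synthetic-data generator: construction invariants, planted effects,
count moments, and seeded determinism."""

import numpy as np
import pytest

from ribotide.io import revcomp, write_annotation, write_fasta
from ribotide.simulate import (
    PlantedEffect,
    SimulationConfig,
    codon_weights_for,
    default_effect_panel,
    generate_genome,
    nb_counts,
    panel_gene_ids,
    plant_effects,
    simulate_reads,
    synthetic_loop_alignment,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestGenomeConstruction:
    def test_gene_count_bookkeeping(self):
        cfg = SimulationConfig(seed=1, n_operons=12, genes_per_operon=5)
        _, annotations, truth = generate_genome(cfg)
        assert len(annotations) == 60
        assert len(truth.gene_ids) == 60

    def test_cds_structure(self, small_sim):
        _, genome, annotations, _ = small_sim
        for ann in annotations:
            assert len(ann) % 3 == 0 and len(ann) >= 150
            cds = genome.subseq(ann.start, ann.end)
            if ann.strand == "-":
                cds = revcomp(cds)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert codons[0] == "ATG"
            assert codons[-1] in STOPS
            assert not any(c in STOPS for c in codons[1:-1])

    def test_alternating_operon_strands(self, small_sim):
        _, _, annotations, _ = small_sim
        strands = {}
        for ann in annotations:
            strands.setdefault(ann.operon_id, ann.strand)
        assert set(strands.values()) == {"+", "-"}

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_operons=2, genes_per_operon=2,
                               gene_length_range=(150, 300))
        for run in ("a", "b"):
            genome, annotations, _ = generate_genome(cfg)
            write_fasta([genome], tmp_path / f"{run}.fasta")
            write_annotation(annotations, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fasta").read_bytes() == \
            (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == \
            (tmp_path / "b.gff3").read_bytes()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(gene_length_range=(151, 300))
        with pytest.raises(ValueError):
            SimulationConfig(rpf_depth=10)
        with pytest.raises(ValueError):
            SimulationConfig(nb_dispersion=0.0)


class TestPlantedEffects:
    def test_combined_fold_product(self):
        cfg = SimulationConfig(seed=3, n_operons=2, genes_per_operon=2,
                               gene_length_range=(150, 300))
        _, annotations, truth = generate_genome(cfg)  # no effects planted
        gid = annotations[0].gene_id
        planted = plant_effects(
            truth, [PlantedEffect(gid, mrna_fold=-4.0, te_fold=-7.0)]
        )
        w_base = truth.expected_weight("MUT", "rpf")[gid]
        w_planted = planted.expected_weight("MUT", "rpf")[gid]
        # a 4-fold mRNA reduction and 7-fold TE reduction compound to 28x
        assert w_planted == pytest.approx(w_base / 28.0)

    def test_empty_effect_list_is_identity(self, small_sim):
        *_, truth = small_sim
        out = plant_effects(truth, [])
        assert out.table.equals(truth.table)

    def test_unknown_gene_rejected(self, small_sim):
        *_, truth = small_sim
        with pytest.raises(KeyError):
            plant_effects(truth, [PlantedEffect("xyz")])

    def test_fold_magnitude_validated(self):
        with pytest.raises(ValueError):
            PlantedEffect("g", mrna_fold=0.5)
        with pytest.raises(ValueError):
            PlantedEffect("g", start_depletion=0.9)

    def test_default_panel_roles(self, small_sim):
        _, _, annotations, truth = small_sim
        roles = panel_gene_ids(annotations)
        table = plant_effects(truth, default_effect_panel(annotations)).table
        assert table.loc[roles["cadB_like"], "te_fold"] == -7.0
        assert table.loc[roles["cadB_like"], "start_depletion"] == 5.0
        assert table.loc[roles["adiY_like"], "te_fold"] == -4.0
        assert table.loc[roles["gadA_like"], "mrna_fold"] == 14.0


class TestCounts:
    def test_negative_binomial_moments(self):
        rng = np.random.default_rng(3)
        mu, disp, n = 500.0, 0.1, 4000
        draws = np.array(
            [nb_counts(np.array([mu]), disp, rng)[0] for _ in range(n)],
            dtype=float,
        )
        expected_var = mu + disp * mu**2
        # mean within 5 SD of its sampling distribution
        assert abs(draws.mean() - mu) < 5 * np.sqrt(expected_var / n)
        assert draws.var() == pytest.approx(expected_var, rel=0.15)

    def test_shared_factor_couples_assays(self):
        rng = np.random.default_rng(4)
        mu = np.full(2000, 300.0)
        factor = rng.gamma(10.0, 0.1, size=2000)
        a = nb_counts(mu, 0.1, rng, shared_factor=factor)
        b = nb_counts(mu, 0.1, rng, shared_factor=factor)
        assert np.corrcoef(a, b)[0, 1] > 0.5


class TestReadSimulation:
    def test_read_lengths_within_support(self, small_sim, tmp_path):
        cfg, genome, annotations, truth = small_sim
        manifest = simulate_reads(genome, annotations, truth, cfg, tmp_path)
        fastq = tmp_path / manifest.iloc[0]["path"]
        lengths = {
            len(line.strip())
            for i, line in enumerate(fastq.open())
            if i % 4 == 1
        }
        assert lengths and all(20 <= n <= 40 for n in lengths)

    def test_seeded_determinism_byte_identical(self, small_sim, tmp_path):
        cfg, genome, annotations, truth = small_sim
        m1 = simulate_reads(genome, annotations, truth, cfg, tmp_path / "a")
        m2 = simulate_reads(genome, annotations, truth, cfg, tmp_path / "b")
        for name in m1["path"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_manifest_covers_design(self, small_sim, tmp_path):
        cfg, genome, annotations, truth = small_sim
        manifest = simulate_reads(genome, annotations, truth, cfg, tmp_path)
        assert len(manifest) == 12
        assert set(manifest["condition"]) == {"WT", "MUT"}
        assert set(manifest["assay"]) == {"rna", "rpf"}
        assert (manifest.groupby(["condition", "assay"]).size() == 3).all()

    def test_start_depletion_thins_first_codons(self, small_sim):
        """With start_depletion=5 the mutant's A-site mass in codons 1-5 is
        about one fifth of the wild-type mass (simulation oracle)."""
        cfg, genome, annotations, truth = small_sim
        roles = panel_gene_ids(annotations)
        ann = next(a for a in annotations
                   if a.gene_id == roles["cadB_like"])
        rng = np.random.default_rng(5)
        fractions = {}
        for condition in ("WT", "MUT"):
            w = codon_weights_for(truth, genome, ann, condition)
            draws = rng.choice(len(w), size=200_000, p=w / w.sum())
            fractions[condition] = np.mean(draws < 5)
        ratio = fractions["MUT"] / fractions["WT"]
        assert ratio == pytest.approx(1 / 5, rel=0.25)

    def test_truth_round_trip(self, small_sim, tmp_path):
        import pandas.testing as pdt

        *_, truth = small_sim
        truth.to_tsv(tmp_path / "gt.tsv")
        loaded = type(truth).from_tsv(tmp_path / "gt.tsv")
        pdt.assert_frame_equal(loaded.table, truth.table, check_exact=False)
        assert loaded.codon_pause == truth.codon_pause


def test_synthetic_loop_alignment_is_rectangular_and_basic_rich():
    records = synthetic_loop_alignment(n_seqs=40, seed=0)
    lengths = {len(s) for _, s in records}
    assert len(records) == 40 and len(lengths) == 1
    joined = "".join(s for _, s in records)
    basic = sum(joined.count(a) for a in "KRH")
    acidic = sum(joined.count(a) for a in "DE")
    assert basic > 5 * max(acidic, 1)
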