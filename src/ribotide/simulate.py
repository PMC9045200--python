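"""Synthetic two-condition ribosome-profiling datasets with known truth.

The generator emulates the study design the analysis assumes: a compact
bacterial chromosome of operon-organized CDSs, and 2 conditions (WT and a
constriction-region ribosome mutant, MUT) x 3 replicates x 2 assays (RPF and
RNA), with

* negative-binomial gene-level counts, realized as gamma-Poisson with the
  gamma factor shared per (gene, replicate index) across assays and
  conditions - same harvest batch, same biology - which is what makes
  replicate pairs covary the way the SD-of-ratio formula corrects for;
* planted signed mRNA and TE fold changes between conditions;
* ribosome A-site positions drawn per codon with multiplicative dwell
  weights (codon-specific pausing) and a start-region depletion factor that
  thins the first five codons in the mutant;
* RPF reads anchored so that the nucleotide 12 from the 3' end (counting the
  3'-terminal base as 1) is the middle base of the sampled A-site codon,
  matching the mapper's offset convention exactly.

Everything is driven by one root seed; identical configurations produce
byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diffte import signed_to_ratio
from .io import (
    GeneAnnotation,
    GenomeSequence,
    revcomp,
    write_annotation,
    write_fasta,
)

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)
CONDITIONS = ("WT", "MUT")
ASSAYS = ("rna", "rpf")
ASITE_OFFSET = 12  # nt from the 3' end, 3'-terminal base counted as 1
START_WINDOW_CODONS = 5
EDGE_PAD = 100  # random padding at both chromosome ends so reads always fit
INTRAGENIC_GAP = 12  # nt between genes inside an operon
QUALITY_CHAR = "~"  # highest Sanger quality; never used analytically


def default_read_length_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Footprint lengths 20-40 nt, discretized Gaussian peaked at 28 nt."""
    lengths = np.arange(20, 41)
    weights = np.exp(-0.5 * ((lengths - 28) / 2.0) ** 2)
    return lengths, weights / weights.sum()


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    n_operons: int = 12
    genes_per_operon: int = 5
    gene_length_range: tuple[int, int] = (150, 1200)
    intergenic_length: int = 50
    replicates_per_group: int = 3
    rpf_depth: int = 200_000
    rna_depth: int = 200_000
    nb_dispersion: float = 0.1
    base_expression_sigma: float = 1.0
    read_lengths: tuple[np.ndarray, np.ndarray] = field(
        default_factory=default_read_length_distribution
    )

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo < 30 or hi < lo:
            raise ValueError(
                "gene_length_range must be multiples of 3 with 30 <= lo <= hi"
            )
        if self.rpf_depth < 1000 or self.rna_depth < 1000:
            raise ValueError("depths must be >= 1000 reads/sample")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lengths, probs = self.read_lengths
        if np.min(lengths) < 20 or np.max(lengths) > 40:
            raise ValueError("read-length support must lie within [20, 40]")
        if not math.isclose(float(np.sum(probs)), 1.0, rel_tol=1e-9):
            raise ValueError("read-length probabilities must sum to 1")
        if self.n_operons < 1 or self.genes_per_operon < 1:
            raise ValueError("need at least one operon with one gene")
        if self.replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")


@dataclass(frozen=True)
class PlantedEffect:
    """Condition effect for one gene, in the signed-fold convention.

    ``mrna_fold`` scales the mutant's expected mRNA mean (and, through it,
    the RPF mean); ``te_fold`` additionally scales the mutant RPF mean;
    ``start_depletion`` divides the mutant A-site weight of the first five
    codons; ``codon_pause`` multiplies mutant dwell weights per codon.
    ``base_expression`` optionally pins the gene's baseline abundance weight
    so an effect gene cannot land on a barely expressed locus.
    """

    gene_id: str
    mrna_fold: float = 1.0
    te_fold: float = 1.0
    start_depletion: float = 1.0
    codon_pause: dict[str, float] = field(default_factory=dict)
    base_expression: float | None = None

    def __post_init__(self) -> None:
        if abs(self.mrna_fold) < 1 or abs(self.te_fold) < 1:
            raise ValueError("signed folds must have magnitude >= 1")
        if self.start_depletion < 1:
            raise ValueError("start_depletion must be >= 1")


class GroundTruth:
    """Per-gene planted parameters; the oracle for parameter recovery."""

    COLUMNS = (
        "base_expression",
        "te_baseline",
        "mrna_fold",
        "te_fold",
        "start_depletion",
    )

    def __init__(self, table: pd.DataFrame,
                 codon_pause: dict[str, dict[str, float]] | None = None):
        self.table = table
        self.codon_pause = codon_pause or {g: {} for g in table.index}

    @classmethod
    def baseline(cls, gene_ids: list[str], base_expression: np.ndarray
                 ) -> "GroundTruth":
        table = pd.DataFrame(
            {
                "base_expression": base_expression,
                "te_baseline": 1.0,
                "mrna_fold": 1.0,
                "te_fold": 1.0,
                "start_depletion": 1.0,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return cls(table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.table.copy(), {g: dict(m) for g, m in self.codon_pause.items()}
        )

    def expected_weight(self, condition: str, assay: str) -> pd.Series:
        """Unnormalized expected abundance per gene for one sample cell."""
        t = self.table
        w = t["base_expression"].copy()
        if assay == "rpf":
            w = w * t["te_baseline"]
        if condition == "MUT":
            w = w * t["mrna_fold"].map(signed_to_ratio)
            if assay == "rpf":
                w = w * t["te_fold"].map(signed_to_ratio)
        return w

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["codon_pause"] = [
            ";".join(f"{c}:{v}" for c, v in sorted(self.codon_pause[g].items()))
            or "."
            for g in out.index
        ]
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        table = pd.read_csv(path, sep="\t", index_col="gene_id")
        pause = {}
        for g, encoded in table["codon_pause"].items():
            pause[g] = (
                {}
                if encoded == "."
                else {
                    c: float(v)
                    for c, v in (item.split(":") for item in encoded.split(";"))
                }
            )
        return cls(table.drop(columns=["codon_pause"]), pause)


# ---------------------------------------------------------------------------
# genome construction


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneAnnotation], GroundTruth]:
    """Build the toy chromosome, its CDS annotation, and baseline truth.

    Operons alternate strand; each CDS starts ATG, ends with a stop, and
    contains no in-frame internal stop codon.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(0,)))
    lo, hi = config.gene_length_range
    pieces: list[str] = [_random_dna(rng, EDGE_PAD)]
    annotations: list[GeneAnnotation] = []
    cursor = EDGE_PAD  # 0-based length so far

    for op_idx in range(config.n_operons):
        operon_id = f"op{op_idx + 1:02d}"
        strand = "+" if op_idx % 2 == 0 else "-"
        gene_seqs = []
        for g_idx in range(config.genes_per_operon):
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            gene_seqs.append(_random_cds(rng, n_codons))
        gaps = [_random_dna(rng, INTRAGENIC_GAP)
                for _ in range(config.genes_per_operon - 1)]

        block_parts: list[str] = []
        offsets: list[tuple[int, int]] = []  # 0-based [a, b] within block
        pos = 0
        for i, seq in enumerate(gene_seqs):
            block_parts.append(seq)
            offsets.append((pos, pos + len(seq) - 1))
            pos += len(seq)
            if i < len(gaps):
                block_parts.append(gaps[i])
                pos += len(gaps[i])
        block = "".join(block_parts)
        if strand == "-":
            block_genomic = revcomp(block)
        else:
            block_genomic = block

        for i, (a, b) in enumerate(offsets):
            gene_id = f"{operon_id}_g{i + 1}"
            if strand == "+":
                start = cursor + a + 1
                end = cursor + b + 1
            else:
                start = cursor + (len(block) - 1 - b) + 1
                end = cursor + (len(block) - 1 - a) + 1
            annotations.append(
                GeneAnnotation(gene_id, operon_id, "chr1", start, end, strand)
            )
        pieces.append(block_genomic)
        cursor += len(block)
        if op_idx < config.n_operons - 1:
            pieces.append(_random_dna(rng, config.intergenic_length))
            cursor += config.intergenic_length

    pieces.append(_random_dna(rng, EDGE_PAD))
    genome = GenomeSequence("chr1", "".join(pieces))

    rng_expr = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,))
    )
    base = rng_expr.lognormal(mean=0.0, sigma=config.base_expression_sigma,
                              size=len(annotations))
    truth = GroundTruth.baseline([a.gene_id for a in annotations], base)
    annotations.sort(key=lambda a: a.start)
    # keep truth rows in annotation order
    truth.table = truth.table.loc[[a.gene_id for a in annotations]]
    truth.codon_pause = {a.gene_id: {} for a in annotations}
    return genome, annotations, truth


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    if n_codons < 3:
        raise ValueError("CDS needs start, one internal codon, and stop")
    internal = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOPS[int(rng.integers(len(STOPS)))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in internal) + stop


# ---------------------------------------------------------------------------
# planted effects


def plant_effects(truth: GroundTruth,
                  effects: list[PlantedEffect]) -> GroundTruth:
    """Return a new truth with the listed condition effects applied."""
    out = truth.copy()
    for eff in effects:
        if eff.gene_id not in out.table.index:
            raise KeyError(f"unknown gene_id {eff.gene_id!r}")
        out.table.loc[eff.gene_id, "mrna_fold"] = float(eff.mrna_fold)
        out.table.loc[eff.gene_id, "te_fold"] = float(eff.te_fold)
        out.table.loc[eff.gene_id, "start_depletion"] = float(
            eff.start_depletion
        )
        if eff.base_expression is not None:
            out.table.loc[eff.gene_id, "base_expression"] = float(
                eff.base_expression
            )
        if eff.codon_pause:
            out.codon_pause[eff.gene_id] = {
                **out.codon_pause[eff.gene_id],
                **{c: float(v) for c, v in eff.codon_pause.items()},
            }
    return out


def default_effect_panel(annotations: list[GeneAnnotation]
                         ) -> list[PlantedEffect]:
    """The standard four-detector panel plus a mutant-wide AGA pause.

    Mirrors the affected-gene archetypes of the study system: a cadB-like
    gene (mRNA down 4x, TE down 7x, strong start-codon depletion), an
    adiY-like gene (TE down 4x, milder start depletion), a gadA-like gene
    (mRNA up 14x), and a well-expressed pause exemplar. The AGA dwell factor
    of 2 is a property of the mutant ribosome and therefore applies to every
    gene in the mutant condition.
    """
    by_operon: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_operon.setdefault(ann.operon_id, []).append(ann)
    operons = sorted(by_operon)
    if len(operons) < 4:
        raise ValueError("default panel needs at least 4 operons")

    def first_gene(op: str) -> str:
        genes = sorted(by_operon[op], key=lambda a: a.gene_id)
        return genes[0].gene_id

    panel_ids = [first_gene(op) for op in operons[:4]]
    effects = [
        PlantedEffect(panel_ids[0], mrna_fold=-4.0, te_fold=-7.0,
                      start_depletion=5.0, base_expression=2.0),
        PlantedEffect(panel_ids[1], te_fold=-4.0, start_depletion=3.0,
                      base_expression=2.0),
        PlantedEffect(panel_ids[2], mrna_fold=14.0, base_expression=1.0),
        PlantedEffect(panel_ids[3], base_expression=3.0),
    ]
    # mutant-ribosome-wide rare-codon pause
    done = set(panel_ids)
    effects = [
        replace(e, codon_pause={"AGA": 2.0}) for e in effects
    ] + [
        PlantedEffect(ann.gene_id, codon_pause={"AGA": 2.0})
        for ann in annotations
        if ann.gene_id not in done
    ]
    return effects


PANEL_ROLES = ("cadB_like", "adiY_like", "gadA_like", "pause_exemplar")


def panel_gene_ids(annotations: list[GeneAnnotation]) -> dict[str, str]:
    """Role -> gene_id map for the default effect panel."""
    by_operon: dict[str, list[str]] = {}
    for ann in annotations:
        by_operon.setdefault(ann.operon_id, []).append(ann.gene_id)
    operons = sorted(by_operon)
    ids = [sorted(by_operon[op])[0] for op in operons[:4]]
    return dict(zip(PANEL_ROLES, ids))


# ---------------------------------------------------------------------------
# read simulation


def nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator,
              shared_factor: np.ndarray | None = None) -> np.ndarray:
    """Gamma-Poisson counts: marginally NB(mean mu, var mu + disp*mu^2).

    When ``shared_factor`` is given it supplies the gamma draw (mean 1,
    variance ``dispersion``), so the biological factor can be shared across
    assays/conditions of one replicate.
    """
    mu = np.asarray(mu, dtype=float)
    if shared_factor is None:
        shared_factor = rng.gamma(1.0 / dispersion, dispersion, size=mu.shape)
    return rng.poisson(mu * shared_factor)


def _cds_sequence(genome: GenomeSequence, ann: GeneAnnotation) -> str:
    seq = genome.subseq(ann.start, ann.end)
    return revcomp(seq) if ann.strand == "-" else seq


def _codon_weights(cds: str, pause: dict[str, float],
                   start_depletion: float,
                   window: int = START_WINDOW_CODONS) -> np.ndarray:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    w = np.array([pause.get(c, 1.0) for c in codons], dtype=float)
    w[: min(window, len(w))] /= start_depletion
    return w


def codon_weights_for(truth: GroundTruth, genome: GenomeSequence,
                      ann: GeneAnnotation, condition: str) -> np.ndarray:
    """Mutant-condition A-site codon weights (WT is uniform)."""
    cds = _cds_sequence(genome, ann)
    if condition == "WT":
        return np.ones(len(cds) // 3)
    row = truth.table.loc[ann.gene_id]
    return _codon_weights(
        cds, truth.codon_pause[ann.gene_id], float(row["start_depletion"])
    )


def simulate_reads(
    genome: GenomeSequence,
    annotations: list[GeneAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
    outdir: str | Path,
) -> pd.DataFrame:
    """Write the 12 FASTQ files plus manifest.tsv; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids = [a.gene_id for a in annotations]
    ann_by_id = {a.gene_id: a for a in annotations}

    # shared per-(gene, replicate) biological factors
    rng_bio = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2,))
    )
    shared = rng_bio.gamma(
        1.0 / config.nb_dispersion,
        config.nb_dispersion,
        size=(len(gene_ids), config.replicates_per_group),
    )

    lengths, length_probs = config.read_lengths
    rows = []
    sample_idx = 0
    for condition in CONDITIONS:
        for assay in ASSAYS:
            depth = config.rna_depth if assay == "rna" else config.rpf_depth
            weights = truth.expected_weight(condition, assay).to_numpy()
            mu = depth * weights / weights.sum()
            for rep in range(1, config.replicates_per_group + 1):
                sample_id = f"{condition}_{assay}_rep{rep}"
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed,
                                           spawn_key=(3, sample_idx))
                )
                counts = nb_counts(mu, config.nb_dispersion, rng,
                                   shared_factor=shared[:, rep - 1])
                path = outdir / f"{sample_id}.fastq"
                n = _write_sample(
                    path, sample_id, genome, ann_by_id, gene_ids, counts,
                    truth, condition, assay, lengths, length_probs, rng,
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "replicate": rep,
                        "assay": assay,
                        "path": path.name,
                        "n_reads": n,
                    }
                )
                sample_idx += 1

    manifest = pd.DataFrame(rows).set_index("sample_id")
    manifest.to_csv(outdir / "manifest.tsv", sep="\t")
    return manifest


def _write_sample(
    path: Path,
    sample_id: str,
    genome: GenomeSequence,
    ann_by_id: dict[str, GeneAnnotation],
    gene_ids: list[str],
    counts: np.ndarray,
    truth: GroundTruth,
    condition: str,
    assay: str,
    lengths: np.ndarray,
    length_probs: np.ndarray,
    rng: np.random.Generator,
) -> int:
    seq = genome.sequence
    chunks: list[str] = []
    read_no = 0
    for gid, count in zip(gene_ids, counts):
        count = int(count)
        if count == 0:
            continue
        ann = ann_by_id[gid]
        read_lens = rng.choice(lengths, size=count, p=length_probs)
        if assay == "rpf":
            w = codon_weights_for(truth, genome, ann, condition)
            codons = rng.choice(len(w), size=count, p=w / w.sum())
            if ann.strand == "+":
                asite = ann.start + 3 * codons + 1
                ends = asite + (ASITE_OFFSET - 1)
                starts = ends - read_lens + 1
            else:
                asite = ann.end - 3 * codons - 1
                starts = asite - (ASITE_OFFSET - 1)
                ends = starts + read_lens - 1
        else:
            # 5' start uniform over the CDS, clipped so the read fits inside
            span = ann.end - ann.start + 1
            max_start = span - read_lens  # inclusive 0-based offset bound
            offsets = rng.integers(0, max_start + 1)
            if ann.strand == "+":
                starts = ann.start + offsets
                ends = starts + read_lens - 1
            else:
                ends = ann.end - offsets
                starts = ends - read_lens + 1
        for s, e in zip(starts, ends):
            frag = seq[s - 1 : e]
            if ann.strand == "-":
                frag = revcomp(frag)
            read_no += 1
            chunks.append(
                f"@{sample_id}:{read_no:07d}\n{frag}\n+\n"
                f"{QUALITY_CHAR * len(frag)}\n"
            )
    path.write_text("".join(chunks))
    return read_no


# ---------------------------------------------------------------------------
# synthetic protein-loop alignment (logo fixture)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def synthetic_loop_alignment(n_seqs: int = 60, seed: int = 0
                             ) -> list[tuple[str, str]]:
    """A designed stand-in for the exit-tunnel loop alignment (synthetic).

    Emulates the qualitative features of the constriction-region loops of
    uL4/uL22 across bacteria: most columns strongly conserved, basic residues
    (K/R/H) enriched, acidic residues (D/E) avoided, one highly variable
    column mimicking the uL22 position-90 site, and one column with gaps.
    The real multi-species alignment is not deposited; per-column numbers
    here carry no biological meaning beyond these designed contrasts.
    """
    rng = np.random.default_rng(seed)
    basic = "KRH"
    # (dominant residue, dominant frequency) per column; None = variable
    design: list[tuple[str | None, float]] = [
        ("K", 0.95), ("G", 0.90), ("R", 0.85), ("A", 0.80), (None, 0.0),
        ("R", 0.90), ("T", 0.75), ("K", 0.95), ("G", 0.85), ("W", 0.90),
    ]
    non_acidic = [a for a in AA20 if a not in "DE"]
    seqs = []
    for i in range(n_seqs):
        chars = []
        for col, (dominant, freq) in enumerate(design):
            if dominant is None:  # the variable "position 90" column
                chars.append(rng.choice(list(basic + "QSTNAG")))
            elif rng.random() < freq:
                chars.append(dominant)
            else:
                chars.append(rng.choice(non_acidic))
        # a ragged C-terminal column: ~20% gaps
        chars.append("-" if rng.random() < 0.2 else "L")
        seqs.append((f"seq{i + 1:03d}", "".join(chars)))
    return seqs


def write_alignment_fasta(records: list[tuple[str, str]],
                          path: str | Path) -> None:
    with Path(path).open("w") as out:
        for name, seq in records:
            out.write(f">{name}\n{seq}\n")
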