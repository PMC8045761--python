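"""Planted-truth simulator for the 2 genotype x 2 condition x 2 fraction design.

The generator emulates the study design the pipeline targets: two genotypes
(wild type and a mutant in which the stress response is abolished), control
and cold conditions, total and polysomal RNA fractions, two replicates per
cell. Genes are planted into four classes:

* NULL — flat everywhere;
* COLD_TX — a transcriptional cold response in the wild type, visible in both
  fractions (polysome loading follows transcript abundance);
* COLD_TL — a purely translational cold response: the polysomal fraction
  moves, total RNA stays flat;
* NT_GENOTYPE — a constitutive genotype effect: the mutant's control-condition
  cells are shifted in both fractions.

Mutant cold responses are scaled by ``mutant_attenuation`` on the log-fold
scale (0 = abolished, 1 = identical to wild type). Replicate noise is
multiplicative log-normal with a fixed coefficient of variation.

Transcript models are generated alongside: i.i.d. uniform bases, the -3/+4
context overwritten to force a drawn Kozak class, and an ATG...TAA cassette
written into the UTR with probability ``uorf_prob``. Sequences are rescanned
after construction, so the recorded truth reflects realized (not merely
planted) uORF content — background ATGs arise by chance exactly as in real
UTRs.

All randomness flows from a single seed through numpy SeedSequence spawning:
stream (0,) drives the transcriptome, stream (1,) the signal matrix, so each
output is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .gene_sets import GeneSetLabel
from .io import Condition, DesignCell, Fraction, Genotype, SampleMeta, SignalMatrix, TranscriptModel
from .seq_features import KozakCategory, UorfMode, find_uorfs, kozak_call

__all__ = [
    "PlantedClass",
    "SimParams",
    "GeneTruth",
    "SimTruth",
    "simulate_transcriptome",
    "simulate_signals",
    "evaluate_recovery",
    "benchmark_params",
]


class PlantedClass(str, Enum):
    NULL = "NULL"
    COLD_TX = "COLD_TX"
    COLD_TL = "COLD_TL"
    NT_GENOTYPE = "NT_GENOTYPE"


_CLASS_ORDER = [
    PlantedClass.NULL,
    PlantedClass.COLD_TX,
    PlantedClass.COLD_TL,
    PlantedClass.NT_GENOTYPE,
]
_KOZAK_ORDER = [
    KozakCategory.STRONG,
    KozakCategory.ADEQUATE,
    KozakCategory.WEAK,
    KozakCategory.NO_UTR,
]


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions. Defaults emulate the study design directly:

    two replicates per cell, fold effects between 1.5 and 3, an abolished
    mutant response, 10% replicate CV, baselines log-normal around a median
    signal of ~55 (the magnitude range of typical normalized signal tables),
    and 5'-UTR feature proportions near the genome-wide background
    (strong/adequate/weak/no-UTR = 34/44.5/10.6/10.8%, ~50% of UTRs with a
    uORF, mean UTR length 100 nt).
    """

    n_genes: int = 2000
    class_probs: tuple[float, float, float, float] = (0.90, 0.05, 0.05, 0.0)
    effect_range: tuple[float, float] = (1.5, 3.0)
    mutant_attenuation: float = 0.0
    noise_cv: float = 0.1
    n_reps: int = 2
    baseline_logmean: float = 4.0
    baseline_logsd: float = 1.0
    kozak_probs: tuple[float, float, float, float] = (0.34, 0.445, 0.106, 0.108)
    uorf_prob: float = 0.5
    utr_len_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.effect_range[0] < 1:
            raise ValueError("effect_range lower bound must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0 <= self.mutant_attenuation <= 1:
            raise ValueError("mutant_attenuation must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.uorf_prob > 0 and self.utr_len_mean < 12:
            raise ValueError(
                "utr_len_mean too small to host a planted uORF (need >= 12)"
            )

    @property
    def kozak_probs_normalized(self) -> np.ndarray:
        p = np.asarray(self.kozak_probs, dtype=float)
        return p / p.sum()


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    planted_class: PlantedClass
    direction: int  # +1, -1, or 0 for NULL
    wt_fold: float  # magnitude >= 1; 1.0 for NULL
    mut_fold: float
    kozak_category: KozakCategory
    uorf_planted: bool
    n_uorfs_realized: int


@dataclass
class SimTruth:
    genes: list[GeneTruth]
    params: SimParams

    def by_gene(self) -> dict[str, GeneTruth]:
        return {g.gene_id: g for g in self.genes}

    def expected_sets(self) -> dict[GeneSetLabel, set[str]]:
        """Gene sets the pipeline should recover under its own selection rules."""
        sets: dict[GeneSetLabel, set[str]] = {label: set() for label in GeneSetLabel}
        for g in self.genes:
            if g.planted_class is PlantedClass.COLD_TX:
                label = GeneSetLabel.COLD_UP_TX if g.direction > 0 else GeneSetLabel.COLD_DOWN_TX
            elif g.planted_class is PlantedClass.COLD_TL:
                label = GeneSetLabel.COLD_UP_TL if g.direction > 0 else GeneSetLabel.COLD_DOWN_TL
            elif g.planted_class is PlantedClass.NT_GENOTYPE:
                label = GeneSetLabel.NT_UP_TX if g.direction > 0 else GeneSetLabel.NT_DOWN_TX
            else:
                continue
            sets[label].add(g.gene_id)
        return sets


_BASES = np.array(list("ACGT"))
_PURINES = np.array(list("AG"))
_PYRIMIDINES = np.array(list("CT"))
_NON_G = np.array(list("ACT"))


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    if length == 0:
        return []
    return list(rng.choice(_BASES, size=length))


def _force_kozak(
    rng: np.random.Generator, utr: list[str], cds: list[str], category: KozakCategory
) -> None:
    """Overwrite the -3 (UTR) and +4 (CDS) positions in place."""
    if category is KozakCategory.NO_UTR:
        return
    if category is KozakCategory.STRONG:
        utr[-3] = str(rng.choice(_PURINES))
        cds[3] = "G"
    elif category is KozakCategory.WEAK:
        utr[-3] = str(rng.choice(_PYRIMIDINES))
        cds[3] = str(rng.choice(_NON_G))
    else:  # ADEQUATE: exactly one site matches, chosen at random
        if rng.random() < 0.5:
            utr[-3] = str(rng.choice(_PURINES))
            cds[3] = str(rng.choice(_NON_G))
        else:
            utr[-3] = str(rng.choice(_PYRIMIDINES))
            cds[3] = "G"


def simulate_transcriptome(
    params: SimParams,
) -> tuple[list[TranscriptModel], SimTruth]:
    """Generate one representative transcript per gene plus the planted truth.

    UTR lengths are geometric with mean ``utr_len_mean``, floored at 3 nt for
    classes that need a -3 position (and at 9 nt when a uORF cassette is
    planted); genes drawn as NO_UTR get an empty UTR. The CDS is 30 nt:
    ATG + 24 random bases + TAA.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(params.seed, spawn_key=(0,)))
    )
    n = params.n_genes
    classes = rng.choice(len(_CLASS_ORDER), size=n, p=np.asarray(params.class_probs))
    directions = np.where(rng.random(n) < 0.5, 1, -1)
    folds = rng.uniform(*params.effect_range, size=n)
    kozak_idx = rng.choice(4, size=n, p=params.kozak_probs_normalized)
    uorf_flags = rng.random(n) < params.uorf_prob
    utr_lens = rng.geometric(1.0 / params.utr_len_mean, size=n)

    models: list[TranscriptModel] = []
    truths: list[GeneTruth] = []
    width = len(str(n))
    for i in range(n):
        gene_id = f"G{i + 1:0{width}d}"
        planted = _CLASS_ORDER[classes[i]]
        category = _KOZAK_ORDER[kozak_idx[i]]
        if category is KozakCategory.NO_UTR:
            utr_len = 0
            plant_uorf = False
        else:
            plant_uorf = bool(uorf_flags[i])
            utr_len = max(int(utr_lens[i]), 9 if plant_uorf else 3)
        utr = _random_seq(rng, utr_len)
        cds = ["A", "T", "G"] + _random_seq(rng, 24) + ["T", "A", "A"]
        cds[0:3] = list("ATG")
        if plant_uorf:
            # overwrite a 6-nt ATG..TAA cassette clear of the -3 context base
            pos = int(rng.integers(0, utr_len - 8))
            utr[pos : pos + 6] = list("ATGTAA")
        _force_kozak(rng, utr, cds, category)
        utr_s, cds_s = "".join(utr), "".join(cds)
        model = TranscriptModel(f"{gene_id}.1", gene_id, utr_s, cds_s, True)
        realized = find_uorfs(utr_s, cds_s, UorfMode.CONTAINED)
        call = kozak_call(model)
        if planted is PlantedClass.NULL:
            direction, wt_fold, mut_fold = 0, 1.0, 1.0
        else:
            direction = int(directions[i])
            wt_fold = float(folds[i])
            mut_fold = float(wt_fold**params.mutant_attenuation)
        models.append(model)
        truths.append(
            GeneTruth(
                gene_id=gene_id,
                planted_class=planted,
                direction=direction,
                wt_fold=wt_fold,
                mut_fold=mut_fold,
                kozak_category=call.category,
                uorf_planted=plant_uorf,
                n_uorfs_realized=len(realized),
            )
        )
    return models, SimTruth(genes=truths, params=params)


def _design_cells() -> list[DesignCell]:
    return [
        DesignCell(g, c, f)
        for g in (Genotype.WT, Genotype.MUT)
        for c in (Condition.CK, Condition.COLD)
        for f in (Fraction.TOTAL, Fraction.POLY)
    ]


def _cell_fold(truth: GeneTruth, cell: DesignCell) -> float:
    """Multiplicative effect of the planted class on one design cell's mean."""
    cls, d = truth.planted_class, truth.direction
    if cls is PlantedClass.NULL:
        return 1.0
    base = truth.wt_fold**d
    if cls is PlantedClass.COLD_TX:
        if cell.condition is Condition.COLD:
            return base if cell.genotype is Genotype.WT else truth.mut_fold**d
    elif cls is PlantedClass.COLD_TL:
        if cell.condition is Condition.COLD and cell.fraction is Fraction.POLY:
            return base if cell.genotype is Genotype.WT else truth.mut_fold**d
    elif cls is PlantedClass.NT_GENOTYPE:
        if cell.genotype is Genotype.MUT and cell.condition is Condition.CK:
            return base
    return 1.0


def simulate_signals(truth: SimTruth, params: SimParams | None = None) -> SignalMatrix:
    """Replicate signal matrix for the full design from the planted truth.

    Per gene: baseline ~ LogNormal(baseline_logmean, baseline_logsd); each
    design-cell mean is the baseline times the planted multiplicative effect;
    each replicate multiplies the cell mean by LogNormal(0, sigma) noise with
    sigma set so the coefficient of variation equals ``noise_cv``.
    """
    params = params or truth.params
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(params.seed, spawn_key=(1,)))
    )
    cells = _design_cells()
    n = len(truth.genes)
    baselines = rng.lognormal(params.baseline_logmean, params.baseline_logsd, size=n)
    sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))

    samples: list[SampleMeta] = []
    for cell in cells:
        for r in range(1, params.n_reps + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{cell}_{r}",
                    genotype=cell.genotype,
                    condition=cell.condition,
                    fraction=cell.fraction,
                    replicate=r,
                )
            )

    means = np.empty((n, len(cells)))
    for j, cell in enumerate(cells):
        for i, g in enumerate(truth.genes):
            means[i, j] = baselines[i] * _cell_fold(g, cell)
    reps = np.repeat(means, params.n_reps, axis=1)
    if sigma > 0:
        reps = reps * rng.lognormal(0.0, sigma, size=reps.shape)
    return SignalMatrix(
        genes=[g.gene_id for g in truth.genes], samples=samples, values=reps
    )


def evaluate_recovery(
    truth: SimTruth, recovered: Mapping[GeneSetLabel, set[str]]
) -> dict[str, dict[str, float | int | None]]:
    """Precision/recall of recovered sets against the planted expectation.

    Precision is None (undefined) for empty recovered sets; recall is None for
    empty truth sets. Exact tp/fp/fn counts are always reported.
    """
    expected = truth.expected_sets()
    report: dict[str, dict[str, float | int | None]] = {}
    for label in GeneSetLabel:
        want = expected.get(label, set())
        got = set(recovered.get(label, set()))
        tp = len(want & got)
        fp = len(got - want)
        fn = len(want - got)
        report[label.value] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if (tp + fp) else None,
            "recall": tp / (tp + fn) if (tp + fn) else None,
        }
    return report


def benchmark_params(seed: int = 20210331) -> SimParams:
    """The standard recovery benchmark: 2000 genes, 5% transcriptional and 5%
    translational cold responders, folds 1.8-3.0, abolished mutant response,
    10% CV, two replicates."""
    return SimParams(
        n_genes=2000,
        class_probs=(0.90, 0.05, 0.05, 0.0),
        effect_range=(1.8, 3.0),
        mutant_attenuation=0.0,
        noise_cv=0.1,
        n_reps=2,
        seed=seed,
    )
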