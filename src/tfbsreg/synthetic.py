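"""Synthetic promoters and expression with known TFBS ground truth.

The generator plants PWM consensus strings into uniform-background
promoters and draws expression from a linear model on the planted hit
counts: per gene and replicate the log2-scale response is

    intercept + sum_m RC_m * count(gene, m) + Normal(0, noise_sd),

and the stored abundance is 2^response - 1 (clipped at 0), so the
log2(x+1) transform used downstream recovers the linear predictor
exactly in the noiseless limit. Planting consensus strings (rather than
probabilistic draws from the PWM) makes cutoff-based recovery exact: a
planted window always scores MSS = CSS = 1.

Every operation draws from its own independently seeded RNG stream, so
adding one generator call never perturbs another's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import ExpressionMatrix
from .pwm import BASES, PWM
from .scan import FeatureMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_pwms",
    "simulate_promoters",
    "simulate_expression",
    "make_truth",
    "simulate_study",
    "write_fasta",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fixed per-op offsets keep each operation on its own RNG stream
_STREAM = {"pwms": 11, "plant": 13, "promoters": 17, "expression": 19}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[op]])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated promoter/expression scenario."""

    promoter_length: int
    gene_ids: list[str]
    planted_hits: dict[str, list[tuple[str, int, str]]]  # gene -> (pwm, pos, strand)
    true_coefficients: dict[str, float]  # pwm id -> RC
    intercept: float
    noise_sd: float
    seed: int

    def validate(self, pwms: Sequence[PWM]) -> None:
        widths = {p.id: p.width for p in pwms}
        for gene, hits in self.planted_hits.items():
            for pwm_id, pos, strand in hits:
                if pwm_id not in self.true_coefficients:
                    raise ValueError(
                        f"planted PWM {pwm_id!r} has no true coefficient"
                    )
                if pwm_id not in widths:
                    raise ValueError(f"planted PWM {pwm_id!r} not provided")
                if not 0 <= pos <= self.promoter_length - widths[pwm_id]:
                    raise ValueError(
                        f"gene {gene!r}: planted position {pos} out of range"
                    )
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")

    def planted_features(self, pwm_ids: Sequence[str]) -> FeatureMatrix:
        """Planted-occurrence counts as a gene x PWM feature matrix."""
        values = pd.DataFrame(
            0,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(pwm_ids),
            dtype=int,
        )
        for gene, hits in self.planted_hits.items():
            for pwm_id, _, _ in hits:
                values.loc[gene, pwm_id] += 1
        return FeatureMatrix(values)

    def linear_predictor(self, features: FeatureMatrix) -> np.ndarray:
        coefs = np.array(
            [self.true_coefficients.get(m, 0.0) for m in features.tfbs_ids]
        )
        return self.intercept + features.values.to_numpy(float) @ coefs

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_hits"] = {
            g: [tuple(h) for h in hits] for g, hits in d["planted_hits"].items()
        }
        return cls(**d)


def simulate_pwms(
    n_motifs: int,
    width_range: tuple[int, int] | int,
    seed: int,
    sharpness: float = 10.0,
) -> list[PWM]:
    """Draw sharp random PWMs with distinct ids M001, M002, ...

    Each position is Dirichlet-distributed with one dominant base
    (concentration ``sharpness`` vs 0.5 elsewhere), so the consensus base
    is always attainable with probability above the 0.25 background.
    Widths are drawn uniformly from ``width_range`` (inclusive); widths
    below 5 are rejected because a 5-position core must exist.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if isinstance(width_range, int):
        width_range = (width_range, width_range)
    lo, hi = width_range
    if lo < 5:
        raise ValueError(
            f"minimum motif width is 5 (a 5-position core must exist); got {lo}"
        )
    if hi < lo:
        raise ValueError("width_range must be (low, high) with low <= high")
    rng = _rng(seed, "pwms")
    pwms = []
    for i in range(n_motifs):
        w = int(rng.integers(lo, hi + 1))
        dominant = rng.integers(0, 4, size=w)
        alpha = np.full((w, 4), 0.5)
        alpha[np.arange(w), dominant] = sharpness
        freq = np.vstack([rng.dirichlet(a) for a in alpha])
        # force the intended dominant base to be the argmax
        for j in range(w):
            if freq[j].argmax() != dominant[j]:
                k = freq[j].argmax()
                freq[j, [dominant[j], k]] = freq[j, [k, dominant[j]]]
        pwm_id = f"M{i + 1:03d}"
        pwms.append(PWM(pwm_id, freq, tf_names=(f"TF{i + 1}",)))
    return pwms


def simulate_promoters(
    truth: SyntheticTruth, pwms: Sequence[PWM]
) -> dict[str, str]:
    """Uniform-background promoters with consensus strings planted.

    Minus-strand plants write the reverse complement of the consensus on
    the plus strand. Overlapping plants on one promoter are an error
    naming the offending gene.
    """
    truth.validate(pwms)
    by_id = {p.id: p for p in pwms}
    rng = _rng(truth.seed, "promoters")
    promoters: dict[str, str] = {}
    for gene in truth.gene_ids:
        seq = rng.choice(list(BASES), size=truth.promoter_length)
        occupied: list[tuple[int, int]] = []
        for pwm_id, pos, strand in truth.planted_hits.get(gene, []):
            w = by_id[pwm_id].width
            for s, e in occupied:
                if pos < e and pos + w > s:
                    raise ValueError(
                        f"gene {gene!r}: planted hits overlap at position {pos}"
                    )
            occupied.append((pos, pos + w))
            cons = by_id[pwm_id].consensus()
            if strand == "-":
                cons = cons.translate(_COMPLEMENT)[::-1]
            seq[pos:pos + w] = list(cons)
        promoters[gene] = "".join(seq)
    return promoters


def simulate_expression(
    truth: SyntheticTruth,
    features: FeatureMatrix,
    n_replicates: int,
    condition: str = "treated",
) -> ExpressionMatrix:
    """Expression replicates from the linear TFBS model.

    Per gene and replicate: log2-scale response = intercept +
    sum RC*feature + Normal(0, noise_sd); abundance = 2^response - 1
    clipped at 0. Replicates differ only by noise.
    """
    if n_replicates < 2:
        raise ValueError(
            "n_replicates must be >= 2 (the DE test needs replication)"
        )
    if list(features.gene_ids) != list(truth.gene_ids):
        raise ValueError("feature rows do not align with truth.gene_ids")
    rng = _rng(truth.seed, "expression")
    mu = truth.linear_predictor(features)
    n_genes = len(truth.gene_ids)
    resp = mu[:, None] + rng.normal(
        0.0, truth.noise_sd, size=(n_genes, n_replicates)
    )
    abundance = np.clip(np.exp2(resp) - 1.0, 0.0, None)
    samples = [f"{condition}_{r + 1}" for r in range(n_replicates)]
    values = pd.DataFrame(
        abundance, index=pd.Index(truth.gene_ids, name="gene_id"), columns=samples
    )
    design = {s: (condition, r + 1) for r, s in enumerate(samples)}
    return ExpressionMatrix(values, design)


def make_truth(
    gene_ids: Sequence[str],
    pwms: Sequence[PWM],
    true_coefficients: Mapping[str, float],
    promoter_length: int = 1200,
    intercept: float = 3.0,
    noise_sd: float = 0.5,
    plant_rate: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Randomly plant motif occurrences and package the ground truth.

    Each (gene, PWM) pair receives a Poisson(``plant_rate``) number of
    occurrences at uniform non-overlapping positions on random strands;
    an occurrence that cannot be placed without overlap after 50 draws is
    dropped. PWMs missing from ``true_coefficients`` get RC 0 (planted
    but inert — nulls for specificity checks).
    """
    rng = _rng(seed, "plant")
    coefs = {p.id: float(true_coefficients.get(p.id, 0.0)) for p in pwms}
    planted: dict[str, list[tuple[str, int, str]]] = {}
    for gene in gene_ids:
        occupied: list[tuple[int, int]] = []
        hits: list[tuple[str, int, str]] = []
        for pwm in pwms:
            for _ in range(rng.poisson(plant_rate)):
                for _attempt in range(50):
                    pos = int(rng.integers(0, promoter_length - pwm.width + 1))
                    if all(pos >= e or pos + pwm.width <= s for s, e in occupied):
                        occupied.append((pos, pos + pwm.width))
                        strand = "+" if rng.random() < 0.5 else "-"
                        hits.append((pwm.id, pos, strand))
                        break
        planted[gene] = hits
    return SyntheticTruth(
        promoter_length=promoter_length,
        gene_ids=list(gene_ids),
        planted_hits=planted,
        true_coefficients=coefs,
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_study(
    pwms: Sequence[PWM],
    n_genes: int = 300,
    coefficients_A: Mapping[str, float] | None = None,
    coefficients_B: Mapping[str, float] | None = None,
    promoter_length: int = 1200,
    intercept: float = 3.0,
    noise_sd: float = 0.5,
    plant_rate: float = 1.0,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[SyntheticTruth, dict[str, str], ExpressionMatrix]:
    """Two treatments plus control sharing one promoter set.

    Control expression comes from the intercept alone (all RCs zero);
    conditions A and B use their own coefficient maps on the same planted
    features, emulating two transductions read against one control.
    Returns (truth for condition A, promoters, combined expression).
    """
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    truth_a = make_truth(
        gene_ids, pwms, coefficients_A or {}, promoter_length=promoter_length,
        intercept=intercept, noise_sd=noise_sd, plant_rate=plant_rate, seed=seed,
    )
    promoters = simulate_promoters(truth_a, pwms)
    features = truth_a.planted_features([p.id for p in pwms])

    def _variant(coefs: Mapping[str, float], sub_seed: int) -> SyntheticTruth:
        t = SyntheticTruth(**{**asdict(truth_a)})
        t.true_coefficients = {p.id: float(coefs.get(p.id, 0.0)) for p in pwms}
        t.seed = sub_seed
        return t

    parts = []
    designs: dict[str, tuple[str, int]] = {}
    for cond, coefs, sub in (
        ("control", {}, seed * 3 + 1),
        ("condA", coefficients_A or {}, seed * 3 + 2),
        ("condB", coefficients_B or {}, seed * 3 + 3),
    ):
        em = simulate_expression(_variant(coefs, sub), features, n_replicates, cond)
        parts.append(em.values)
        designs.update(em.design)
    combined = ExpressionMatrix(pd.concat(parts, axis=1), designs)
    return truth_a, promoters, combined


def write_fasta(promoters: Mapping[str, str], path: str) -> None:
    """One record per gene, header = gene id."""
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
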