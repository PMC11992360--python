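"""Simulated LLR distributions, FNR-calibrated thresholds, and
importance-sampled false-positive rates.

Pairs of genotypes are simulated directly from each relationship's
per-locus observed-pair distribution (error channel included), which is
equivalent to simulating explicit pedigrees under locus independence.
False-positive rates far beyond direct Monte-Carlo reach are estimated
by importance sampling from the numerator relationship: for a target
comparison num/den with natural-log statistic Lambda,

    P(Lambda > eta | den) = E_num[ exp(-Lambda) 1{Lambda > eta} ],

because exp(-Lambda) is exactly the den/num likelihood ratio of the
sampled pair.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqs import AlleleFrequencySet
from .kinship import (
    RELATIONSHIPS,
    LLRConfig,
    RelationshipModel,
    genotype_pairs,
    locus_llr_table,
    observed_pair_matrix,
)

#: comparisons reported in a threshold table, in order
COMPARISONS: tuple[tuple[str, str], ...] = (
    ("SELF", "U"),
    ("PO", "U"),
    ("FS", "U"),
    ("FS", "HS"),
    ("PO", "FS"),
)


@dataclass
class LLRDistribution:
    """Sorted simulated Lambda samples for pairs of one true relationship."""

    true_model: str
    comparison: str
    samples: np.ndarray
    seed: int
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))

    @property
    def n_pairs(self) -> int:
        return self.samples.size


@dataclass
class ThresholdRow:
    comparison: str
    eta: float
    target_fnr: float
    realized_fnr: float
    fpr: float
    fpr_se: float
    n_pairs: int
    n_importance: int
    no_exceedances: bool = False


@dataclass
class ThresholdTable:
    """Per-comparison LLR cutoffs with FNR and importance-sampled FPR."""

    rows: list[ThresholdRow]
    seed: int
    epsilon: float

    def get(self, comparison: str) -> ThresholdRow:
        for row in self.rows:
            if row.comparison == comparison:
                return row
        raise KeyError(comparison)

    def eta(self, comparison: str) -> float:
        return self.get(comparison).eta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "epsilon": self.epsilon,
            "rows": [vars(r) for r in self.rows],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            payload = json.load(fh)
        rows = [ThresholdRow(**r) for r in payload["rows"]]
        return cls(rows=rows, seed=payload["seed"], epsilon=payload["epsilon"])


# ---------------------------------------------------------------------------
# simulation primitives
# ---------------------------------------------------------------------------

def simulate_joint_genotypes(
    freqs: AlleleFrequencySet,
    true_model: RelationshipModel,
    epsilon: float,
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (g1, g2) genotype-index draws from the observed-pair law."""
    out = []
    for locus in freqs:
        joint = observed_pair_matrix(locus.freqs, true_model, epsilon)
        g = joint.shape[0]
        flat = joint.ravel()
        flat = flat / flat.sum()  # guard rounding
        idx = rng.choice(g * g, size=n_pairs, p=flat)
        out.append((idx // g, idx % g))
    return out


def _llr_from_draws(
    freqs: AlleleFrequencySet,
    draws: list[tuple[np.ndarray, np.ndarray]],
    cfg: LLRConfig,
) -> np.ndarray:
    n = draws[0][0].size
    lam = np.zeros(n)
    for locus, (g1, g2) in zip(freqs, draws):
        table = locus_llr_table(locus.freqs, cfg)
        lam += table[g1, g2]
    return lam


def simulate_llr_profiles(
    freqs: AlleleFrequencySet,
    true_model: RelationshipModel,
    comparisons: list[tuple[str, str]] | None = None,
    epsilon: float = 0.005,
    n_pairs: int = 10000,
    seed: int = 0,
    log_base: str = "e",
) -> dict[str, np.ndarray]:
    """All comparison LLRs evaluated on one common set of simulated pairs.

    Each pair is drawn once from the true relationship's observed-pair
    law and scored under every requested num/den comparison, as needed
    to push simulated pairs through the hierarchical classifier.
    """
    comparisons = comparisons or list(COMPARISONS)
    rng = np.random.default_rng(seed)
    draws = simulate_joint_genotypes(freqs, true_model, epsilon, n_pairs, rng)
    out = {}
    for num_name, den_name in comparisons:
        cfg = LLRConfig(
            RELATIONSHIPS[num_name],
            RELATIONSHIPS[den_name],
            epsilon=epsilon,
            log_base=log_base,
        )
        out[cfg.name] = _llr_from_draws(freqs, draws, cfg)
    return out


def simulate_llr_distribution(
    freqs: AlleleFrequencySet,
    true_model: RelationshipModel,
    cfg: LLRConfig,
    n_pairs: int = 10000,
    seed: int = 0,
) -> LLRDistribution:
    """Simulate Lambda for ``n_pairs`` pairs of the given true relationship."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    draws = simulate_joint_genotypes(freqs, true_model, cfg.epsilon, n_pairs, rng)
    lam = _llr_from_draws(freqs, draws, cfg)
    return LLRDistribution(
        true_model=true_model.name,
        comparison=cfg.name,
        samples=lam,
        seed=seed,
        log_base=cfg.log_base,
    )


# ---------------------------------------------------------------------------
# thresholds and tail probabilities
# ---------------------------------------------------------------------------

def threshold_at_fnr(dist: LLRDistribution | np.ndarray, fnr: float) -> float:
    """Empirical FNR-quantile threshold.

    eta is the largest sample value v with (#samples strictly below v)/n
    <= fnr; pairs are declared positive when Lambda > eta, so at most a
    fraction ~fnr of true-relationship samples fall at or below eta.
    """
    if not 0.0 < fnr < 1.0:
        raise ValueError("fnr must be in (0, 1)")
    samples = dist.samples if isinstance(dist, LLRDistribution) else np.sort(
        np.asarray(dist, dtype=float)
    )
    n = samples.size
    if fnr * n < 1:
        warnings.warn(
            f"fnr*n = {fnr * n:.3g} < 1: threshold set to the minimum sample",
            stacklevel=2,
        )
        return float(samples[0])
    uniq = np.unique(samples)
    frac_below = np.searchsorted(samples, uniq, side="left") / n
    return float(uniq[frac_below <= fnr][-1])


@dataclass
class FPREstimate:
    value: float
    se: float
    n_samples: int
    n_exceedances: int

    @property
    def no_exceedances(self) -> bool:
        return self.n_exceedances == 0


def estimate_fpr_importance(
    freqs: AlleleFrequencySet,
    numerator: RelationshipModel,
    denominator: RelationshipModel,
    eta: float,
    epsilon: float = 0.005,
    n_samples: int = 100000,
    seed: int = 0,
    log_base: str = "e",
) -> FPREstimate:
    """Importance-sampled P(Lambda_num/den > eta | denominator relationship).

    Pairs are drawn from the numerator relationship's observed-pair
    distribution and reweighted by the den/num likelihood ratio.  The
    returned standard error is the draw-level Monte-Carlo SE; when no
    draw exceeds eta the estimate is 0 with SE 0 and
    ``no_exceedances`` set.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = LLRConfig(numerator, denominator, epsilon=epsilon, log_base=log_base)
    rng = np.random.default_rng(seed)
    draws = simulate_joint_genotypes(freqs, numerator, epsilon, n_samples, rng)
    lam = _llr_from_draws(freqs, draws, cfg)
    # natural-log Lambda for the weights regardless of reporting base
    lam_nat = lam / cfg.log_scale
    exceed = lam > eta
    weights = np.zeros(n_samples)
    weights[exceed] = np.exp(-lam_nat[exceed])
    value = float(weights.mean())
    se = float(weights.std(ddof=1) / math.sqrt(n_samples)) if n_samples > 1 else 0.0
    return FPREstimate(
        value=value, se=se, n_samples=n_samples, n_exceedances=int(exceed.sum())
    )


def estimate_fpr_direct(
    freqs: AlleleFrequencySet,
    cfg: LLRConfig,
    eta: float,
    n_samples: int,
    seed: int = 0,
) -> FPREstimate:
    """Direct Monte-Carlo P(Lambda > eta | denominator): the naive oracle."""
    rng = np.random.default_rng(seed)
    draws = simulate_joint_genotypes(freqs, cfg.denominator, cfg.epsilon, n_samples, rng)
    lam = _llr_from_draws(freqs, draws, cfg)
    hits = lam > eta
    value = float(hits.mean())
    se = float(hits.std(ddof=1) / math.sqrt(n_samples)) if n_samples > 1 else 0.0
    return FPREstimate(
        value=value, se=se, n_samples=n_samples, n_exceedances=int(hits.sum())
    )


def build_threshold_table(
    freqs: AlleleFrequencySet,
    epsilon: float = 0.005,
    fnr: float = 0.01,
    n_pairs: int = 10000,
    n_importance: int = 100000,
    seed: int = 0,
    po_fs_eta: float | None = 3.0,
    log_base: str = "e",
) -> ThresholdTable:
    """Thresholds and importance-sampled FPRs for the standard comparisons.

    For each comparison num/den the numerator-relationship Lambda
    distribution is simulated, eta set at the target FNR, and the FPR
    against the denominator importance-sampled.  PO/FS uses the fixed
    cutoff ``po_fs_eta`` (default 3) instead of an FNR quantile; pass
    ``po_fs_eta=None`` to calibrate it like the others.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for (num_name, den_name), child in zip(
        COMPARISONS, ss.spawn(len(COMPARISONS))
    ):
        num = RELATIONSHIPS[num_name]
        den = RELATIONSHIPS[den_name]
        cfg = LLRConfig(num, den, epsilon=epsilon, log_base=log_base)
        sim_seed, is_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        dist = simulate_llr_distribution(freqs, num, cfg, n_pairs=n_pairs, seed=sim_seed)
        if num_name == "PO" and den_name == "FS" and po_fs_eta is not None:
            eta = float(po_fs_eta)
        else:
            eta = threshold_at_fnr(dist, fnr)
        realized_fnr = float(np.mean(dist.samples <= eta))
        fpr = estimate_fpr_importance(
            freqs, num, den, eta, epsilon=epsilon,
            n_samples=n_importance, seed=is_seed, log_base=log_base,
        )
        rows.append(
            ThresholdRow(
                comparison=cfg.name,
                eta=eta,
                target_fnr=fnr,
                realized_fnr=realized_fnr,
                fpr=fpr.value,
                fpr_se=fpr.se,
                n_pairs=n_pairs,
                n_importance=n_importance,
                no_exceedances=fpr.no_exceedances,
            )
        )
    return ThresholdTable(rows=rows, seed=seed, epsilon=epsilon)


def expected_false_positives(n_comparisons: float, fpr: float) -> float:
    """Expected count of false positives across ``n_comparisons`` pairs."""
    return float(n_comparisons) * float(fpr)
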