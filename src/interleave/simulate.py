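"""Synthetic genomes with known ground truth.

The generator lays genes along chromosomes with log-normal lengths and
gaps, assigns strand, feature class and metabolic-cycle phase, links
expression to phase and condition, and can plant three kinds of structure
that the analysis modules are meant to detect:

* an excess of convergent 3'-end overlaps over the orientation-blind
  baseline (``planted_overlap_enrichment``; 1.0 = no excess, attributes
  exchangeable within chromosomes — exactly the shuffle null's regime);
* spatial clustering of cycling genes along gene order, as a first-order
  Markov chain over cycling status (``ymc_clustering``; 0 = independent);
* phase-linked condition switching: a fraction of OX/RC genes respond to
  the glucose-to-galactose shift with a planted log fold change, OX down
  and RC up.

Overlap-excess bookkeeping: strands are assigned independently, so a
random adjacent pair is convergent ((+,-) in genomic order) with
probability 1/4.  A convergent pair is made to overlap with probability
``convergent_overlap_rate``; other orientations overlap with a background
rate chosen so that the convergent-overlap count exceeds its shuffle-null
expectation by the requested enrichment factor (values above 4 are
geometrically impossible: even if every overlap were convergent the ratio
cannot exceed 1/(1/4)).

Coverage synthesis places, per feature, Poisson per-base signal on its own
strand with total mass proportional to expression, plus opposite-strand
signal sized so that the expected antisense fraction of the feature's
total signal equals ``antisense_fraction``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .io import (EXPR_PREFIX, FEATURE_CLASSES, FeatureTable,
                 StrandedCoverage, YMC_PHASES)
from .factors import FactorOccupancyMatrix


@dataclass
class SyntheticGenomeParams:
    """Full parameterisation of the generator; defaults are the
    yeast-scale preset (~16 chromosomes x ~410 features ~ 6,600 features,
    class and phase mixes echoing the budding-yeast annotation)."""

    seed: int = 0
    n_chrom: int = 16
    genes_per_chrom: int = 410
    # feature geometry (bp)
    gene_length_log_mean: float = log(1200.0)
    gene_length_log_sd: float = 0.55
    min_gene_length: int = 60
    gap_length_log_mean: float = log(220.0)
    gap_length_log_sd: float = 0.9
    # attribute mixes
    class_proportions: tuple[float, ...] = (0.70, 0.15, 0.12, 0.03)
    ymc_proportions: tuple[float, ...] = (0.20, 0.05, 0.31, 0.44)
    ymc_clustering: float = 0.3
    # convergent 3'-overlap structure
    convergent_overlap_rate: float = 0.2
    planted_overlap_enrichment: float = 1.0
    background_overlap_rate: float | None = None
    overlap_length_log_mean: float = log(92.0)
    overlap_length_log_sd: float = 0.6
    # expression model (two conditions)
    conditions: tuple[str, str] = ("glu", "gal")
    expr_base_log_mean: float = log(12.0)
    expr_base_log_sd: float = 0.9
    expr_cond_log_sd: float = 0.3
    phase_log_fc: dict = field(default_factory=lambda: {
        "OX": -1.32, "RB": 0.0, "RC": 1.32, "NC": 0.0})
    phase_response_rate: float = 0.5
    # steady-state (secondary) fold-change model
    stability_noise_log_sd: float = 0.25
    stability_divergent_rate: float = 0.10
    # coverage synthesis
    antisense_fraction: float = 0.2
    coverage_depth: float = 3.0
    # factor occupancy
    n_factors: int = 202
    factor_baseline_rate: float = 0.10
    planted_factors: tuple = ()  # (factor_name, phase-or-id-collection, odds)

    def __post_init__(self):
        if self.n_chrom < 1 or self.genes_per_chrom < 1:
            raise ValueError("need at least one chromosome and one gene")
        for name, probs, labels in (
                ("class_proportions", self.class_proportions,
                 FEATURE_CLASSES),
                ("ymc_proportions", self.ymc_proportions, YMC_PHASES)):
            if len(probs) != len(labels) or not np.isclose(sum(probs), 1.0):
                raise ValueError(f"{name} must be a simplex over {labels}")
        if not 0 <= self.ymc_clustering < 1:
            raise ValueError("ymc_clustering must be in [0, 1)")
        if not 0 <= self.convergent_overlap_rate <= 1:
            raise ValueError("convergent_overlap_rate must be in [0, 1]")
        if not 0 <= self.antisense_fraction < 1:
            raise ValueError("antisense_fraction must be in [0, 1)")
        r = self.planted_overlap_enrichment
        if not 0 < r <= 4:
            raise ValueError("planted_overlap_enrichment must be in (0, 4]")
        if np.exp(self.overlap_length_log_mean) >= \
                np.exp(self.gene_length_log_mean):
            raise ValueError("typical overlap length must be smaller than "
                             "typical gene length")

    @property
    def effective_background_overlap_rate(self) -> float:
        if self.background_overlap_rate is not None:
            return self.background_overlap_rate
        r = self.planted_overlap_enrichment
        p = self.convergent_overlap_rate * (4.0 - r) / (3.0 * r)
        return float(min(p, 1.0))

    @classmethod
    def yeastlike(cls, seed: int = 0, **overrides) -> "SyntheticGenomeParams":
        """The default yeast-scale preset (override any field)."""
        return cls(seed=seed, **overrides)

    def replace(self, **changes) -> "SyntheticGenomeParams":
        return dataclasses.replace(self, **changes)


def _rng(params: SyntheticGenomeParams, stream: int,
         seed: int | None) -> np.random.Generator:
    base = params.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def _markov_cycling(rng, m: int, pi_c: float, rho: float) -> np.ndarray:
    """Cycling/non-cycling labels along gene order with persistence rho
    (stationary cycling probability stays pi_c)."""
    if rho == 0 or pi_c in (0.0, 1.0):
        return rng.random(m) < pi_c
    p_cc = pi_c + rho * (1 - pi_c)   # stay cycling
    p_nc = pi_c * (1 - rho)          # enter cycling from non-cycling
    u = rng.random(m)
    out = np.empty(m, dtype=bool)
    out[0] = u[0] < pi_c
    for i in range(1, m):
        out[i] = u[i] < (p_cc if out[i - 1] else p_nc)
    return out


def generate_genome(params: SyntheticGenomeParams, seed: int | None = None
                    ) -> tuple[FeatureTable, dict]:
    """Draw a feature table plus a ground-truth record of planted effects."""
    rng = _rng(params, 0, seed)
    p_conv = params.convergent_overlap_rate
    p_back = params.effective_background_overlap_rate
    classes = np.asarray(FEATURE_CLASSES)
    phases = np.asarray(YMC_PHASES)
    pi_c = 1.0 - params.ymc_proportions[YMC_PHASES.index("NC")]
    cycling_probs = np.asarray(params.ymc_proportions[:3], dtype=float)
    if pi_c > 0:
        cycling_probs = cycling_probs / cycling_probs.sum()
    cond_a, cond_b = params.conditions
    phase_fc = np.array([params.phase_log_fc.get(ph, 0.0)
                         for ph in YMC_PHASES])

    frames = []
    truth_overlaps = []
    truth_responders = []
    for c in range(params.n_chrom):
        chrom = f"chr{c + 1:02d}"
        m = params.genes_per_chrom
        lengths = np.maximum(
            np.rint(rng.lognormal(params.gene_length_log_mean,
                                  params.gene_length_log_sd, m)),
            params.min_gene_length).astype(np.int64)
        strands = np.where(rng.random(m) < 0.5, "+", "-")
        gaps = np.rint(rng.lognormal(params.gap_length_log_mean,
                                     params.gap_length_log_sd, m)
                       ).astype(np.int64)
        step = gaps.copy()  # step[i] = signed gap preceding gene i
        ov_len = np.zeros(m, dtype=np.int64)
        if m > 1:
            conv = (strands[:-1] == "+") & (strands[1:] == "-")
            p_ov = np.where(conv, p_conv, p_back)
            ov_mask = rng.random(m - 1) < p_ov
            draw = np.rint(rng.lognormal(params.overlap_length_log_mean,
                                         params.overlap_length_log_sd,
                                         m - 1)).astype(np.int64)
            cap = np.minimum(lengths[:-1], lengths[1:]) - 1
            draw = np.clip(draw, 1, cap)
            ov_len[1:] = np.where(ov_mask, draw, 0)
            step[1:] = np.where(ov_mask, -ov_len[1:], gaps[1:])
        starts = np.empty(m, dtype=np.int64)
        starts[0] = gaps[0] + 1
        if m > 1:
            starts[1:] = starts[0] + np.cumsum(lengths[:-1] + step[1:] + 0)
        ends = starts + lengths - 1

        klass = classes[rng.choice(len(classes), m,
                                   p=np.asarray(params.class_proportions))]
        cyc = _markov_cycling(rng, m, pi_c, params.ymc_clustering)
        phase = np.full(m, "NC", dtype=object)
        n_cyc = int(cyc.sum())
        if n_cyc:
            phase[cyc] = phases[:3][rng.choice(3, n_cyc, p=cycling_probs)]
        phase_idx = np.array([YMC_PHASES.index(p) for p in phase])

        base = rng.normal(params.expr_base_log_mean,
                          params.expr_base_log_sd, m)
        respond = (np.isin(phase, ("OX", "RC"))
                   & (rng.random(m) < params.phase_response_rate))
        delta = np.where(respond, phase_fc[phase_idx], 0.0)
        log_a = base - delta / 2 + rng.normal(0, params.expr_cond_log_sd, m)
        log_b = base + delta / 2 + rng.normal(0, params.expr_cond_log_sd, m)

        ids = np.array([f"{chrom}_g{i + 1:04d}" for i in range(m)])
        frames.append(pd.DataFrame({
            "feature_id": ids,
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "strand": strands,
            "feature_class": klass,
            "ymc_phase": phase,
            EXPR_PREFIX + cond_a: np.round(np.exp(log_a), 6),
            EXPR_PREFIX + cond_b: np.round(np.exp(log_b), 6),
        }))
        for i in np.flatnonzero(ov_len > 0):
            truth_overlaps.append({
                "left": ids[i - 1], "right": ids[i],
                "overlap_bp": int(ov_len[i]),
                "convergent": bool(strands[i - 1] == "+"
                                   and strands[i] == "-"),
            })
        truth_responders.extend(ids[respond].tolist())

    table = FeatureTable(pd.concat(frames, ignore_index=True))
    truth = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(params).items()},
        "planted_overlap_enrichment": params.planted_overlap_enrichment,
        "background_overlap_rate": p_back,
        "overlaps": truth_overlaps,
        "n_overlaps": len(truth_overlaps),
        "responders": truth_responders,
    }
    return table, truth


def generate_coverage(table: FeatureTable, params: SyntheticGenomeParams,
                      condition: str | None = None, seed: int | None = None
                      ) -> tuple[StrandedCoverage, StrandedCoverage]:
    """Poisson per-base sense/antisense tracks for one condition.

    Expected sense mass per feature is ``coverage_depth x expression``;
    expected antisense mass is ``f/(1-f)`` times that, so antisense makes
    up fraction ``f = antisense_fraction`` of the feature's expected total
    signal.
    """
    rng = _rng(params, 1, seed)
    if condition is None:
        condition = table.conditions[0]
    f = params.antisense_fraction
    anti_scale = f / (1.0 - f)
    sizes = {chrom: int(table.df.iloc[sl]["end"].max()) + 200
             for chrom, sl in table.chrom_slices()}
    plus = {c: np.zeros(n) for c, n in sizes.items()}
    minus = {c: np.zeros(n) for c, n in sizes.items()}
    expr = table.expr(condition)
    for i, feat in enumerate(table.features()):
        mass = params.coverage_depth * expr[i]
        if mass <= 0:
            continue
        length = feat.length
        rate = mass / length
        sense_track = plus if feat.strand == "+" else minus
        anti_track = minus if feat.strand == "+" else plus
        lo, hi = feat.start - 1, feat.end
        sense_track[feat.chrom][lo:hi] += rng.poisson(rate, length)
        if anti_scale > 0:
            anti_track[feat.chrom][lo:hi] += rng.poisson(rate * anti_scale,
                                                         length)
    return (StrandedCoverage("+", plus), StrandedCoverage("-", minus))


def generate_factor_matrix(table: FeatureTable,
                           params: SyntheticGenomeParams,
                           seed: int | None = None
                           ) -> tuple[FactorOccupancyMatrix, dict]:
    """Bernoulli occupancy matrix over ORF-T promoters with planted
    enrichments.

    Each planted entry is ``(factor_name, gene_set, odds)`` where
    ``gene_set`` is either a phase name (OX/RB/RC) selecting the cycling
    genes of that phase, or an explicit collection of feature ids; inside
    the set the binding odds are multiplied by ``odds``.
    """
    rng = _rng(params, 2, seed)
    orf = table.df[table.df["feature_class"] == "ORF_T"]
    genes = orf["feature_id"].to_numpy()
    if len(genes) == 0:
        raise ValueError("no ORF_T features to build a promoter matrix for")
    names = [f"F{i + 1:03d}" for i in range(params.n_factors)]
    base = params.factor_baseline_rate
    probs = np.full((params.n_factors, len(genes)), base)
    truth = []
    phase_by_gene = orf.set_index("feature_id")["ymc_phase"]
    for factor_name, selector, odds in params.planted_factors:
        if factor_name not in names:
            raise ValueError(f"unknown planted factor {factor_name!r}")
        if isinstance(selector, str):
            members = set(phase_by_gene.index[phase_by_gene == selector])
        else:
            members = set(selector)
        row = names.index(factor_name)
        p_in = base * odds / (1.0 - base + base * odds)
        probs[row, np.isin(genes, list(members))] = p_in
        truth.append({"factor": factor_name, "n_set": len(members),
                      "odds": float(odds), "p_in": float(p_in)})
    bound = rng.random(probs.shape) < probs
    matrix = FactorOccupancyMatrix(
        pd.DataFrame(bound, index=names, columns=genes))
    return matrix, {"baseline_rate": base, "planted": truth}


def steady_state_fold_changes(table: FeatureTable,
                              params: SyntheticGenomeParams,
                              cond_a: str | None = None,
                              cond_b: str | None = None,
                              pseudocount: float = 0.5,
                              seed: int | None = None) -> pd.Series:
    """Synthetic steady-state (poly(A)+-like) fold changes per feature.

    Most features track the nascent fold change up to multiplicative
    noise; a ``stability_divergent_rate`` fraction get an independent
    fold change, emulating stability-driven transcript changes.
    """
    rng = _rng(params, 3, seed)
    if cond_a is None or cond_b is None:
        cond_a, cond_b = table.conditions[:2]
    a = table.expr(cond_a)
    b = table.expr(cond_b)
    fc = (b + pseudocount) / (a + pseudocount)
    n = len(fc)
    noise = np.exp(rng.normal(0, params.stability_noise_log_sd, n))
    divergent = rng.random(n) < params.stability_divergent_rate
    independent = np.exp(rng.normal(0, 1.2, n))
    out = np.where(divergent, independent, fc * noise)
    return pd.Series(out, index=table.df["feature_id"].to_numpy(),
                     name="fc_secondary")
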