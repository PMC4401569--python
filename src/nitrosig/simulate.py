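"""Synthetic factorial expression data with planted, recoverable effects.

The generator emulates a wine-fermentation macroarray study: three yeast
strains grown under a low-nitrogen (LN) and a high-nitrogen (HN) regime,
sampled at a handful of time points with two membrane replicates per
condition.  Expression is built additively on the log2 scale,

    log2 x[g, s] = baseline_g + G(strain) + E(time) + GEI(strain, time)
                   + N(regime, time) + Normal(0, noise_sd_log2),

and exported on the linear scale.  Each planted effect class is tracked in a
:class:`GroundTruth` object so downstream screens (ANOVA, correlation, Rank
Product, the biomarker cascade) can be scored against the truth.

Effect classes are disjoint by default:

* genotype (G): one strain shifted by ``effect_size_log2`` at all times;
* environment (E): one time point shifted in every strain and regime;
* interaction (GEI): a zero-sum product contrast ``effect * u_s * v_t`` with
  zero-sum ``u`` and ``v``, so an interaction gene carries no marginal
  strain or stage signal;
* nitrogen-responsive: a linear fold (drawn log-uniformly from
  ``nitrogen_fold_range``) applied under LN from ``nitrogen_onset_h``
  onwards, emulating genes that react once assimilable nitrogen runs out.

A single top-level seed drives independent substreams for flag assignment,
baselines, effect draws, noise and missingness, so e.g. changing
``missing_rate`` never changes which genes carry effects.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_expression",
    "generate_phenotypes",
    "inject_missing",
    "simulate_signature_scenario",
    "write_synthetic_gmt",
    "sample_id",
]


def sample_id(strain: str, regime: str, time_h: int, replicate: int) -> str:
    return f"{strain}_{regime}_{time_h:02d}h_m{replicate}"


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Design constants and effect-planting rates for one synthetic study.

    Defaults reproduce the study layout this package targets: ~5764 probed
    genes, 3 strains x {LN, HN} x {12, 24, 96} h with two membranes per
    condition, genotype/stage/interaction effects of 2.0 log2 units over
    0.25 log2 units of replicate noise, and nitrogen-responsive folds
    between 3 and 25 (the span of the published biomarker panel).
    """

    n_genes: int = 5764
    strains: tuple[str, ...] = ("CEG", "QA23", "VL1")
    regimes: tuple[str, ...] = ("LN", "HN")
    time_points_h: tuple[int, ...] = (12, 24, 96)
    n_replicates: int = 2
    frac_g_effect: float = 0.10
    frac_e_effect: float = 0.12
    frac_gei_effect: float = 0.03
    frac_nitrogen_responsive: float = 0.05
    frac_nitrogen_down: float = 0.25
    effect_size_log2: float = 2.0
    nitrogen_fold_range: tuple[float, float] = (3.0, 25.0)
    nitrogen_onset_h: int = 24
    noise_sd_log2: float = 0.25
    missing_rate: float = 0.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.strains or not self.regimes or not self.time_points_h:
            raise ValueError("factor level lists must be non-empty")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain labels")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in (
            "frac_g_effect",
            "frac_e_effect",
            "frac_gei_effect",
            "frac_nitrogen_responsive",
            "frac_nitrogen_down",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        lo, hi = self.nitrogen_fold_range
        if not (1.0 < lo <= hi):
            raise ValueError("nitrogen_fold_range lower bound must be > 1")
        if self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be positive")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        total = (
            self.frac_g_effect
            + self.frac_e_effect
            + self.frac_gei_effect
            + self.frac_nitrogen_responsive
        )
        if total > 1.0 + 1e-12:
            raise ValueError(
                "effect fractions must sum to <= 1 (effect classes are disjoint)"
            )

    @property
    def n_samples(self) -> int:
        return (
            len(self.strains)
            * len(self.regimes)
            * len(self.time_points_h)
            * self.n_replicates
        )


@dataclasses.dataclass
class GroundTruth:
    """Planted-effect bookkeeping for one simulated dataset.

    ``table`` carries the per-gene flags and folds; the effect arrays allow
    reconstruction of the noise-free expected log2 mean of every
    (gene, strain, regime, time) cell via :meth:`expected_log2`.
    """

    table: pd.DataFrame
    strains: tuple[str, ...]
    regimes: tuple[str, ...]
    time_points_h: tuple[int, ...]
    g_effect: np.ndarray  # (n_genes, n_strains)
    e_effect: np.ndarray  # (n_genes, n_times)
    gei_effect: np.ndarray  # (n_genes, n_strains, n_times)
    n_effect: np.ndarray  # (n_genes, n_regimes, n_times)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def expected_log2(self, strain: str, regime: str, time_h: int) -> np.ndarray:
        """Noise-free expected log2 expression of every gene in one cell."""
        si = self.strains.index(strain)
        ri = self.regimes.index(regime)
        ti = self.time_points_h.index(time_h)
        return (
            self.table["baseline_log2"].to_numpy()
            + self.g_effect[:, si]
            + self.e_effect[:, ti]
            + self.gei_effect[:, si, ti]
            + self.n_effect[:, ri, ti]
        )


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _exact_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """The sample sheet: one row per strain x regime x time x membrane."""
    rows = []
    for strain in config.strains:
        for regime in config.regimes:
            for t in config.time_points_h:
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": sample_id(strain, regime, t, rep),
                            "strain": strain,
                            "regime": regime,
                            "time_h": t,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def generate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one study: (linear expression matrix, design table, truth).

    The matrix is genes x samples on the linear intensity scale with NaN
    marking missing spots; identical (config, seed) gives identical output.
    """
    config.validate()
    rng_assign, rng_base, rng_eff, rng_noise, rng_miss = _streams(config.seed, 5)

    n = config.n_genes
    a = len(config.strains)
    b = len(config.time_points_h)
    r = len(config.regimes)
    genes = pd.Index([f"gene_{i:05d}" for i in range(n)], name="gene_id")

    n_g = _exact_count(config.frac_g_effect, n)
    n_e = _exact_count(config.frac_e_effect, n)
    n_gei = _exact_count(config.frac_gei_effect, n)
    n_nr = _exact_count(config.frac_nitrogen_responsive, n)
    if n_g + n_e + n_gei + n_nr > n:
        raise ValueError("planted effect counts exceed the gene count")
    perm = rng_assign.permutation(n)
    idx_g = np.sort(perm[:n_g])
    idx_e = np.sort(perm[n_g : n_g + n_e])
    idx_gei = np.sort(perm[n_g + n_e : n_g + n_e + n_gei])
    idx_nr = np.sort(perm[n_g + n_e + n_gei : n_g + n_e + n_gei + n_nr])

    baseline = rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    g_eff = np.zeros((n, a))
    e_eff = np.zeros((n, b))
    gei_eff = np.zeros((n, a, b))
    n_eff = np.zeros((n, r, b))

    # genotype: one strain per flagged gene carries the full shift
    g_strain = rng_eff.integers(0, a, size=n_g)
    g_eff[idx_g, g_strain] = config.effect_size_log2

    # environment: one time point shifted across all strains and regimes
    e_time = rng_eff.integers(0, b, size=n_e)
    e_eff[idx_e, e_time] = config.effect_size_log2

    # interaction: zero-sum product contrast over a strain pair and time pair
    for gi in idx_gei:
        s1, s2 = rng_eff.choice(a, size=2, replace=False)
        t1, t2 = rng_eff.choice(b, size=2, replace=False)
        d = config.effect_size_log2
        gei_eff[gi, s1, t1] += d
        gei_eff[gi, s1, t2] -= d
        gei_eff[gi, s2, t1] -= d
        gei_eff[gi, s2, t2] += d

    # nitrogen response: linear fold under LN from the onset time onwards
    lo, hi = config.nitrogen_fold_range
    folds = np.exp(rng_eff.uniform(math.log(lo), math.log(hi), size=n_nr))
    down = rng_eff.random(n_nr) < config.frac_nitrogen_down
    folds = np.where(down, 1.0 / folds, folds)
    ln_idx = config.regimes.index("LN") if "LN" in config.regimes else 0
    onset_cols = [
        j for j, t in enumerate(config.time_points_h) if t >= config.nitrogen_onset_h
    ]
    for fi, gi in enumerate(idx_nr):
        n_eff[gi, ln_idx, onset_cols] = math.log2(folds[fi])

    design = make_design(config)
    log2 = np.empty((n, config.n_samples))
    for col, row in enumerate(design.itertuples(index=False)):
        si = config.strains.index(row.strain)
        ri = config.regimes.index(row.regime)
        ti = config.time_points_h.index(row.time_h)
        log2[:, col] = (
            baseline
            + g_eff[:, si]
            + e_eff[:, ti]
            + gei_eff[:, si, ti]
            + n_eff[:, ri, ti]
        )
    if config.noise_sd_log2 > 0:
        log2 = log2 + rng_noise.normal(0.0, config.noise_sd_log2, log2.shape)

    linear = np.exp2(log2)
    if config.missing_rate > 0:
        mask = rng_miss.random(linear.shape) < config.missing_rate
        linear = np.where(mask, np.nan, linear)

    matrix = pd.DataFrame(linear, index=genes, columns=design["sample_id"].to_list())
    matrix.attrs["scale"] = "linear"

    flags = pd.DataFrame(
        {
            "has_g_effect": np.isin(np.arange(n), idx_g),
            "has_e_effect": np.isin(np.arange(n), idx_e),
            "has_gei_effect": np.isin(np.arange(n), idx_gei),
            "is_nitrogen_responsive": np.isin(np.arange(n), idx_nr),
            "true_fold_LN_over_HN": 1.0,
            "baseline_log2": baseline,
        },
        index=genes,
    )
    flags.loc[genes[idx_nr], "true_fold_LN_over_HN"] = folds
    truth = GroundTruth(
        table=flags,
        strains=config.strains,
        regimes=config.regimes,
        time_points_h=config.time_points_h,
        g_effect=g_eff,
        e_effect=e_eff,
        gei_effect=gei_eff,
        n_effect=n_eff,
    )
    return matrix, design, truth


def inject_missing(matrix: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set each entry missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.shape) < rate
    out = matrix.mask(mask)
    out.attrs["scale"] = matrix.attrs.get("scale", "linear")
    return out


def generate_phenotypes(
    truth: GroundTruth,
    config: SimulationConfig,
    noise_sd: float = 0.0,
    growth_time_h: int | None = None,
    fermentation_time_h: int | None = None,
) -> pd.DataFrame:
    """One phenotype row per strain x regime: mu (1/h), n_rate, mfr.

    Phenotypes are monotone linear functions of planted nitrogen-module
    activity, defined as the mean noise-free expected log2 expression of
    the nitrogen-responsive genes in that strain x regime cell (all genes
    if none are planted).  Growth phenotypes (mu, n_rate) read the module
    at the first time point at or past the nitrogen onset; the
    fermentation phenotype (mfr) reads it at the last time point.  Gaussian
    noise of sd ``noise_sd`` (phenotype units) is added from the config
    seed's phenotype substream, so the table is deterministic.
    """
    config.validate()
    times = config.time_points_h
    if growth_time_h is None:
        past = [t for t in times if t >= config.nitrogen_onset_h]
        growth_time_h = past[0] if past else times[-1]
    if fermentation_time_h is None:
        fermentation_time_h = times[-1]
    module = truth.table["is_nitrogen_responsive"].to_numpy()
    if not module.any():
        module = np.ones(len(truth.table), dtype=bool)

    rows = []
    for strain in config.strains:
        for regime in config.regimes:
            act_growth = truth.expected_log2(strain, regime, growth_time_h)[
                module
            ].mean()
            act_ferm = truth.expected_log2(strain, regime, fermentation_time_h)[
                module
            ].mean()
            rows.append(
                {
                    "strain": strain,
                    "regime": regime,
                    "_act_growth": act_growth,
                    "_act_ferm": act_ferm,
                }
            )
    phen = pd.DataFrame(rows)

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    zg = _z(phen["_act_growth"])
    zf = _z(phen["_act_ferm"])
    # scales loosely matching wine-fermentation magnitudes
    phen["mu"] = 0.18 + 0.04 * zg
    phen["n_rate"] = 15.0 + 4.0 * zg
    phen["mfr"] = 1.8 + 0.5 * zf
    if noise_sd > 0:
        rng = _streams(config.seed, 6)[5]
        for col, scale in (("mu", 0.04), ("n_rate", 4.0), ("mfr", 0.5)):
            phen[col] = phen[col] + rng.normal(0.0, noise_sd * scale, len(phen))
    return phen.drop(columns=["_act_growth", "_act_ferm"])


def simulate_signature_scenario(
    n_genes: int = 2000,
    n_true: int = 40,
    n_decoy: int = 40,
    fold_range: tuple[float, float] = (4.0, 10.0),
    noise_sd_log2: float = 0.25,
    n_replicates: int = 2,
    strains: Sequence[str] = ("CEG", "QA23", "VL1"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A dataset tailored to exercising the biomarker cascade.

    Plants two gene classes at matched linear folds f drawn log-uniformly
    from ``fold_range`` (c = log2 f):

    * ``true``: +c under LN from 24 h on, flat in HN — genuine
      nitrogen-limitation responders (LN-induced, HN-silent);
    * ``decoy``: +2c under LN and +c under HN from 24 h on — show the same
      LN/HN fold at the selected times but also respond over time under
      HN, so a specific cascade must exclude them.

    Returns (linear matrix, design, roles) where roles has columns
    ``role`` in {true, decoy, null} and ``fold``.  The design includes the
    36 h time point used for the slow strain's limitation sample.
    """
    if n_true + n_decoy > n_genes:
        raise ValueError("planted classes exceed n_genes")
    config = SimulationConfig(
        n_genes=n_genes,
        strains=tuple(strains),
        time_points_h=(12, 24, 36, 96),
        n_replicates=n_replicates,
        noise_sd_log2=noise_sd_log2,
        seed=seed,
    )
    rng_assign, rng_base, rng_eff, rng_noise, _ = _streams(seed, 5)
    perm = rng_assign.permutation(n_genes)
    idx_true = np.sort(perm[:n_true])
    idx_decoy = np.sort(perm[n_true : n_true + n_decoy])
    baseline = rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    lo, hi = fold_range
    folds_true = np.exp(rng_eff.uniform(math.log(lo), math.log(hi), n_true))
    folds_decoy = np.exp(rng_eff.uniform(math.log(lo), math.log(hi), n_decoy))

    design = make_design(config)
    genes = pd.Index([f"gene_{i:05d}" for i in range(n_genes)], name="gene_id")
    log2 = np.tile(baseline[:, None], (1, config.n_samples))
    for col, row in enumerate(design.itertuples(index=False)):
        late = row.time_h >= 24
        if not late:
            continue
        if row.regime == "LN":
            log2[idx_true, col] += np.log2(folds_true)
            log2[idx_decoy, col] += 2.0 * np.log2(folds_decoy)
        else:
            log2[idx_decoy, col] += np.log2(folds_decoy)
    if noise_sd_log2 > 0:
        log2 = log2 + rng_noise.normal(0.0, noise_sd_log2, log2.shape)
    matrix = pd.DataFrame(
        np.exp2(log2), index=genes, columns=design["sample_id"].to_list()
    )
    matrix.attrs["scale"] = "linear"

    roles = pd.DataFrame({"role": "null", "fold": 1.0}, index=genes)
    roles.loc[genes[idx_true], "role"] = "true"
    roles.loc[genes[idx_true], "fold"] = folds_true
    roles.loc[genes[idx_decoy], "role"] = "decoy"
    roles.loc[genes[idx_decoy], "fold"] = folds_decoy
    return matrix, design, roles


def write_synthetic_gmt(
    truth: GroundTruth,
    path,
    n_random_categories: int = 20,
    category_size: tuple[int, int] = (20, 120),
    seed: int = 0,
) -> None:
    """Write a synthetic GMT annotation: planted modules + random categories.

    The planted categories (nitrogen module, genotype module, stage module)
    give enrichment tests something real to find; the random categories
    provide the null background.  Purely synthetic stand-ins for curated
    functional annotation.
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids.to_numpy()
    cats: list[tuple[str, str, list[str]]] = []
    for name, col in (
        ("planted_nitrogen_module", "is_nitrogen_responsive"),
        ("planted_genotype_module", "has_g_effect"),
        ("planted_stage_module", "has_e_effect"),
    ):
        members = list(genes[truth.table[col].to_numpy()])
        if members:
            cats.append((name, "synthetic planted module", members))
    lo, hi = category_size
    for i in range(n_random_categories):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        cats.append((f"random_category_{i:02d}", "synthetic random category", members))
    with open(path, "w") as fh:
        for name, desc, members in cats:
            fh.write("\t".join([name, desc, *members]) + "\n")
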