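"""Orchestration of the two evaluation protocols over replicates and designs.

Two simulation protocols share the same breeding template (15 cycles of
reciprocal recurrent genomic selection on two heterotic pools):

* the *gain program* runs the full breeding scheme separately per testcross
  design, so designs are compared on realized hybrid genetic gain; and
* the *accuracy program* runs a single baseline trajectory (every line crossed
  to the same three testers, parents selected on the testcross model applied
  to per-line mean phenotypes) and, at selected cycles, applies every
  configured design to the *same* lines with freshly drawn random testers to
  compare GCA prediction accuracies under identical conditions. Design
  evaluations never feed back into selection.

Seeding is hierarchical: founder genome, locus assignment, trait and pool
formation depend only on (root seed, replicate), so all designs of a replicate
start from identical initial pools.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import breeding, designs, metrics, models
from .genome import GenomeParams, assign_loci, simulate_founder_haplotypes
from .rng import child_rng, derive_int
from .trait import TraitArchitecture, sample_trait

__all__ = [
    "ExperimentConfig",
    "CycleMetrics",
    "SCENARIO_MU_DELTA",
    "PROFILES",
    "cycle_one_pools",
    "run_gain_program",
    "run_accuracy_program",
    "aggregate_replicates",
    "metrics_frame",
]

SCENARIO_MU_DELTA = {"low": 0.1, "medium": 0.5, "high": 0.9}

#: Named scale profiles. "full" is the complete program scale; "desk" trims the
#: population and marker density to reproduce the qualitative results in
#: minutes; "mini" is for smoke tests only.
PROFILES: dict[str, dict] = {
    "full": {},
    "desk": {
        "genome": GenomeParams(n_qtn_per_chr=100, n_snp_per_chr=100),
        "n_crosses": 40,
        "dh_per_cross": 10,
        "n_replicates": 10,
    },
    "mini": {
        "genome": GenomeParams(
            n_chromosomes=3, chr_length_bp=5e7, chr_length_cM=100,
            n_founders=16, n_qtn_per_chr=40, n_snp_per_chr=40,
        ),
        "n_parents": 8,
        "n_crosses": 10,
        "dh_per_cross": 4,
        "n_replicates": 2,
    },
}


@dataclass
class ExperimentConfig:
    """Scenario, design list, scale and seeding of one experiment."""

    scenario: str = "medium"
    designs: tuple = (1, 2, 10)
    n_cycles: int = 15
    eval_cycles: tuple = (1, 2, 3, 5, 10, 15)
    n_replicates: int = 100
    root_seed: int = 1
    genome: GenomeParams = field(default_factory=GenomeParams)
    n_parents: int = 40
    n_crosses: int = 60
    dh_per_cross: int = 20
    formation_generations: int = 3
    var_delta: float = 0.2
    target_var_A: float = 20.0
    H2: float = 0.3
    baseline_testers: int = 3
    n_sample_pairs: int = 100_000
    variance_scaling: str = "genic"
    stratify_families: bool = False
    mu_delta_override: float | None = None
    # test hook: callable(pool_name, truth) -> scores, replacing the genomic
    # predictor during accuracy evaluation; never serialized
    gca_predictor_override: Callable | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_MU_DELTA and self.mu_delta_override is None:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        bad = [c for c in self.eval_cycles if not 1 <= c]
        if bad:
            raise ValueError(f"eval cycles {bad} outside [1, n_cycles]")
        for d in self.designs:
            k = self.design_k(d)
            if k is not None and self.n_lines % k:
                raise ValueError(f"design {d}: {k} testers do not divide "
                                 f"{self.n_lines} lines")

    @property
    def mu_delta(self) -> float:
        if self.mu_delta_override is not None:
            return self.mu_delta_override
        return SCENARIO_MU_DELTA[self.scenario]

    @property
    def n_lines(self) -> int:
        return self.n_crosses * self.dh_per_cross

    def design_k(self, design) -> int | None:
        """Tester count of a design, or None for the incomplete factorial."""
        if design == designs.INCOMPLETE_FACTORIAL:
            return None
        return int(design)

    @staticmethod
    def design_name(design) -> str:
        if design == designs.INCOMPLETE_FACTORIAL:
            return designs.INCOMPLETE_FACTORIAL
        return f"{int(design)}t"

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_profile(cls, profile: str = "desk", **overrides) -> "ExperimentConfig":
        kw = dict(PROFILES[profile])
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("gca_predictor_override")
        d["genome"] = dataclasses.asdict(self.genome)
        for k in ("designs", "eval_cycles"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = GenomeParams(**d["genome"])
        for k in ("designs", "eval_cycles"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class CycleMetrics:
    """One tidy record: per (program, scenario, design, replicate, cycle, pool)."""

    program: str
    scenario: str
    design: str
    replicate: int
    cycle: int
    pool: str = "both"
    gain: float = np.nan
    acc_genomic: float = np.nan
    acc_phenotypic: float = np.nan
    var_gca_f: float = np.nan
    var_gca_m: float = np.nan
    var_sca: float = np.nan
    var_hybrid: float = np.nan
    nei_D: float = np.nan
    heterosis_H: float = np.nan
    frac_fixed_same: float = np.nan
    frac_fixed_opposite: float = np.nan
    sigma2_e: float = np.nan
    H2_realized: float = np.nan


def metrics_frame(rows: Sequence[CycleMetrics]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# replicate setup


@dataclass
class _ReplicateState:
    trait: TraitArchitecture
    pools: breeding.InitialPools
    ff0: float  # full-factorial hybrid mean of the initial pools


def _setup_replicate(cfg: ExperimentConfig, replicate: int) -> _ReplicateState:
    founders = simulate_founder_haplotypes(
        cfg.genome, derive_int(cfg.root_seed, replicate, "genome")
    )
    founders = assign_loci(
        founders, cfg.genome, derive_int(cfg.root_seed, replicate, "loci")
    ).drop_neutral()
    trait = sample_trait(
        founders, cfg.mu_delta, cfg.var_delta, cfg.target_var_A,
        derive_int(cfg.root_seed, replicate, "trait"),
        scaling=cfg.variance_scaling,
    )
    pools = breeding.form_initial_pools(
        founders,
        generations=cfg.formation_generations,
        seed=derive_int(cfg.root_seed, replicate, "formation"),
        n_parents=cfg.n_parents,
        n_crosses=cfg.n_crosses,
        dh_per_cross=cfg.dh_per_cross,
    )
    ff0 = metrics.full_factorial_mean(
        pools.pool_f.qtn_alleles(trait).mean(axis=0),
        pools.pool_m.qtn_alleles(trait).mean(axis=0),
        trait,
    )
    return _ReplicateState(trait=trait, pools=pools, ff0=ff0)


def _advance_pools(
    cfg: ExperimentConfig,
    pool_f: breeding.LinePopulation,
    pool_m: breeding.LinePopulation,
    parents_f: np.ndarray,
    parents_m: np.ndarray,
    seed: int,
    cycle: int,
) -> tuple[breeding.LinePopulation, breeding.LinePopulation]:
    new = []
    for pool, parents, name in ((pool_f, parents_f, "female"), (pool_m, parents_m, "male")):
        rng = child_rng(seed, "advance", name)
        new.append(
            breeding.advance_generation(
                pool.geno[parents], pool.loci, cfg.n_crosses, cfg.dh_per_cross,
                rng, pool=name, cycle=cycle,
            )
        )
    return new[0], new[1]


def cycle_one_pools(
    cfg: ExperimentConfig, replicate: int
) -> tuple[TraitArchitecture, breeding.LinePopulation, breeding.LinePopulation]:
    """Trait and the two cycle-1 line populations of one replicate.

    Runs founder simulation, trait sampling and pool formation, then one
    breeding generation from the initial pools' random parents — the
    populations entering the first cycle of either protocol.
    """
    state = _setup_replicate(cfg, replicate)
    seed = derive_int(cfg.root_seed, replicate, "cycle1")
    lines_f, lines_m = _advance_pools(
        cfg, state.pools.pool_f, state.pools.pool_m,
        state.pools.parents_f, state.pools.parents_m, seed, 1,
    )
    return state.trait, lines_f, lines_m


# ---------------------------------------------------------------------------
# design evaluation: testcross, phenotype, fit, predict


def _phenotyped_testcrosses(
    cand: breeding.LinePopulation,
    opp: breeding.LinePopulation,
    tester_of_line: np.ndarray,
    trait: TraitArchitecture,
    sigma2_e: float,
    seed: int,
    line_idx: np.ndarray | None = None,
) -> breeding.TestcrossSet:
    if line_idx is None:
        line_idx = np.arange(cand.n_lines)
    gv = metrics.hybrid_values_pairs(cand, opp, line_idx, tester_of_line, trait)
    ts = breeding.TestcrossSet(
        line_idx=line_idx,
        tester_idx=tester_of_line,
        genetic_values=gv,
    )
    return breeding.simulate_phenotypes(ts, sigma2_e, seed)


def _predict_pool_sparse(
    cand: breeding.LinePopulation,
    opp: breeding.LinePopulation,
    ts: breeding.TestcrossSet,
) -> np.ndarray:
    """Fit the pool-specific model on one pool's sparse testcrosses and
    predict candidate GCA via the pool-specific GCA allele effects."""
    Z1 = cand.snp_alleles().astype(float)
    Z2 = opp.snp_alleles()[ts.tester_idx].astype(float)
    fit = models.fit_pool_specific_model(ts.phenotypes, Z1, Z2)
    eff = models.gca_marker_effects(
        fit,
        cand.snp_alleles().mean(axis=0),
        opp.snp_alleles().mean(axis=0),
    )
    return models.predict_gca(cand.snp_dosages(), eff.alpha_pool1)


def _evaluate_design(
    cfg: ExperimentConfig,
    design,
    lines_f: breeding.LinePopulation,
    lines_m: breeding.LinePopulation,
    trait: TraitArchitecture,
    sigma2_e: float,
    seed: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Apply one testcross design to both pools.

    Returns per pool name a tuple ``(predicted GCA scores, phenotype of the
    single testcross of each line)``. Every design phenotypes exactly
    ``n_lines`` testcrosses per pool (equal-resources premise).
    """
    k = cfg.design_k(design)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if k is None:  # incomplete factorial: one joint fit predicts both pools
        assign = designs.incomplete_factorial_pairs(
            lines_f.n_lines, lines_m.n_lines, derive_int(seed, "pairs")
        )
        partner = assign.tester_of_line
        ts = _phenotyped_testcrosses(
            lines_f, lines_m, partner, trait, sigma2_e, derive_int(seed, "pheno")
        )
        Z1 = lines_f.snp_alleles().astype(float)
        Z2 = lines_m.snp_alleles()[partner].astype(float)
        fit = models.fit_pool_specific_model(ts.phenotypes, Z1, Z2)
        eff = models.gca_marker_effects(
            fit,
            lines_f.snp_alleles().mean(axis=0),
            lines_m.snp_alleles().mean(axis=0),
        )
        scores_f = models.predict_gca(lines_f.snp_dosages(), eff.alpha_pool1)
        scores_m = models.predict_gca(lines_m.snp_dosages(), eff.alpha_pool2)
        pheno_m = np.empty_like(ts.phenotypes)
        pheno_m[partner] = ts.phenotypes
        out["female"] = (scores_f, ts.phenotypes)
        out["male"] = (scores_m, pheno_m)
        return out

    for cand, opp, name in ((lines_f, lines_m, "female"), (lines_m, lines_f, "male")):
        testers = designs.select_testers(opp, k, derive_int(seed, "testers", name))
        assign = designs.allocate_sparse(
            cand.n_lines, testers, derive_int(seed, "allocate", name),
            family=cand.family if cfg.stratify_families else None,
            design_name=cfg.design_name(design),
        )
        ts = _phenotyped_testcrosses(
            cand, opp, assign.tester_of_line, trait, sigma2_e,
            derive_int(seed, "pheno", name),
        )
        if k == 1:
            fit = models.fit_testcross_model(ts.phenotypes, cand.snp_dosages().astype(float))
            scores = models.predict_gca(cand.snp_dosages(), fit.alpha)
        else:
            scores = _predict_pool_sparse(cand, opp, ts)
        out[name] = (scores, ts.phenotypes)
    return out


# ---------------------------------------------------------------------------
# shared per-cycle metric records


def _divergence_record(
    row: CycleMetrics,
    lines_f: breeding.LinePopulation,
    lines_m: breeding.LinePopulation,
    trait: TraitArchitecture,
    ff0: float,
) -> CycleMetrics:
    pf = lines_f.qtn_alleles(trait).mean(axis=0)
    pm = lines_m.qtn_alleles(trait).mean(axis=0)
    freqs = metrics.AlleleFrequencies(p_female=pf, p_male=pm)
    row.gain = metrics.full_factorial_mean(pf, pm, trait) - ff0
    row.nei_D = metrics.nei_min_distance(freqs)
    row.heterosis_H = metrics.mid_parent_heterosis(freqs, trait)
    row.frac_fixed_same, row.frac_fixed_opposite = metrics.fixed_allele_fractions(freqs)
    return row


def _variance_record(
    row: CycleMetrics,
    lines_f: breeding.LinePopulation,
    lines_m: breeding.LinePopulation,
    trait: TraitArchitecture,
    cfg: ExperimentConfig,
    seed: int,
) -> CycleMetrics:
    vf, vm, vs, vh = metrics.gca_sca_variances(
        lines_f, lines_m, trait, n_sample_pairs=cfg.n_sample_pairs, seed=seed
    )
    row.var_gca_f, row.var_gca_m, row.var_sca, row.var_hybrid = vf, vm, vs, vh
    if row.sigma2_e == row.sigma2_e:  # not NaN
        row.H2_realized = vh / (vh + row.sigma2_e)
    return row


# ---------------------------------------------------------------------------
# protocols


def run_gain_program(
    cfg: ExperimentConfig, design, replicate: int
) -> pd.DataFrame:
    """Run the full breeding program under one testcross design.

    Per cycle and pool: generate lines from the current parents, draw the
    design's testers from the opposite pool, testcross, phenotype with the
    error variance frozen at cycle 1, fit the design's prediction model,
    and select the top parents on predicted GCA. Gain is the full-factorial
    hybrid mean relative to the initial pools.
    """
    state = _setup_replicate(cfg, replicate)
    trait, ff0 = state.trait, state.ff0
    pool_f, pool_m = state.pools.pool_f, state.pools.pool_m
    parents_f, parents_m = state.pools.parents_f, state.pools.parents_m
    dname = cfg.design_name(design)
    sigma2_e = np.nan
    rows: list[CycleMetrics] = []
    if cfg.n_cycles == 0:  # metrics of the initial pools only
        row = CycleMetrics(
            program="gain", scenario=cfg.scenario, design=dname,
            replicate=replicate, cycle=0,
        )
        rows.append(_divergence_record(row, pool_f, pool_m, trait, ff0))
    for cycle in range(1, cfg.n_cycles + 1):
        cseed = derive_int(cfg.root_seed, replicate, "gain", dname, cycle)
        lines_f, lines_m = _advance_pools(
            cfg, pool_f, pool_m, parents_f, parents_m, cseed, cycle
        )
        if cycle == 1:
            sigma2_e = breeding.calibrate_error_variance(
                pool_f.take(parents_f), pool_m.take(parents_m), trait, cfg.H2
            )
        evald = _evaluate_design(cfg, design, lines_f, lines_m, trait, sigma2_e, cseed)
        parents_f = models.select_parents(evald["female"][0], cfg.n_parents)
        parents_m = models.select_parents(evald["male"][0], cfg.n_parents)

        row = CycleMetrics(
            program="gain", scenario=cfg.scenario, design=dname,
            replicate=replicate, cycle=cycle, sigma2_e=sigma2_e,
        )
        row = _divergence_record(row, lines_f, lines_m, trait, ff0)
        if cycle in cfg.eval_cycles:
            row = _variance_record(row, lines_f, lines_m, trait, cfg, cseed)
            truth_f = metrics.true_gca(
                lines_f, lines_m.qtn_alleles(trait).mean(axis=0), trait
            )
            truth_m = metrics.true_gca(
                lines_m, lines_f.qtn_alleles(trait).mean(axis=0), trait
            )
            accs = [
                metrics.prediction_accuracy(evald["female"][0], truth_f),
                metrics.prediction_accuracy(evald["male"][0], truth_m),
            ]
            finite = [a for a in accs if np.isfinite(a)]
            row.acc_genomic = float(np.mean(finite)) if finite else np.nan
        rows.append(row)
        pool_f, pool_m = lines_f, lines_m
    return metrics_frame(rows)


def run_accuracy_program(cfg: ExperimentConfig, replicate: int) -> pd.DataFrame:
    """Run the baseline program and evaluate all designs at the eval cycles.

    The baseline crosses every line with the same three random testers from
    the opposite pool and selects parents on the testcross model fitted to
    per-line mean phenotypes. At each eval cycle every configured design is
    applied to the same lines with fresh random testers; genomic accuracy is
    the correlation of predicted with true GCA, phenotypic accuracy the
    correlation of the single testcross phenotype with true GCA.
    """
    state = _setup_replicate(cfg, replicate)
    trait, ff0 = state.trait, state.ff0
    pool_f, pool_m = state.pools.pool_f, state.pools.pool_m
    parents_f, parents_m = state.pools.parents_f, state.pools.parents_m
    sigma2_e = np.nan
    rows: list[CycleMetrics] = []
    for cycle in range(1, cfg.n_cycles + 1):
        bseed = derive_int(cfg.root_seed, replicate, "baseline", cycle)
        lines_f, lines_m = _advance_pools(
            cfg, pool_f, pool_m, parents_f, parents_m, bseed, cycle
        )
        if cycle == 1:
            sigma2_e = breeding.calibrate_error_variance(
                pool_f.take(parents_f), pool_m.take(parents_m), trait, cfg.H2
            )

        # baseline: all lines x the same `baseline_testers` testers, per pool
        truth: dict[str, np.ndarray] = {}
        for cand, opp, name in ((lines_f, lines_m, "female"), (lines_m, lines_f, "male")):
            testers = designs.select_testers(
                opp, cfg.baseline_testers, derive_int(bseed, "testers", name)
            )
            n = cand.n_lines
            line_idx = np.tile(np.arange(n), len(testers))
            tester_idx = np.repeat(testers, n)
            ts = _phenotyped_testcrosses(
                cand, opp, tester_idx, trait, sigma2_e,
                derive_int(bseed, "pheno", name), line_idx=line_idx,
            )
            # mean testcross performance per line across the common testers
            ybar = ts.phenotypes.reshape(len(testers), n).mean(axis=0)
            fit = models.fit_testcross_model(ybar, cand.snp_dosages().astype(float))
            scores = models.predict_gca(cand.snp_dosages(), fit.alpha)
            if name == "female":
                parents_f = models.select_parents(scores, cfg.n_parents)
            else:
                parents_m = models.select_parents(scores, cfg.n_parents)

        row = CycleMetrics(
            program="accuracy", scenario=cfg.scenario, design="baseline",
            replicate=replicate, cycle=cycle, sigma2_e=sigma2_e,
        )
        row = _divergence_record(row, lines_f, lines_m, trait, ff0)
        if cycle in cfg.eval_cycles:
            row = _variance_record(row, lines_f, lines_m, trait, cfg, bseed)
            truth["female"] = metrics.true_gca(
                lines_f, lines_m.qtn_alleles(trait).mean(axis=0), trait
            )
            truth["male"] = metrics.true_gca(
                lines_m, lines_f.qtn_alleles(trait).mean(axis=0), trait
            )
        rows.append(row)

        if cycle in cfg.eval_cycles:
            for design in cfg.designs:
                eseed = derive_int(
                    cfg.root_seed, replicate, "eval", cycle, cfg.design_name(design)
                )
                evald = _evaluate_design(
                    cfg, design, lines_f, lines_m, trait, sigma2_e, eseed
                )
                for name in ("female", "male"):
                    scores, pheno = evald[name]
                    if cfg.gca_predictor_override is not None:
                        scores = cfg.gca_predictor_override(name, truth[name])
                    rows.append(CycleMetrics(
                        program="accuracy", scenario=cfg.scenario,
                        design=cfg.design_name(design), replicate=replicate,
                        cycle=cycle, pool=name, sigma2_e=sigma2_e,
                        acc_genomic=metrics.prediction_accuracy(scores, truth[name]),
                        acc_phenotypic=metrics.prediction_accuracy(pheno, truth[name]),
                    ))
        pool_f, pool_m = lines_f, lines_m
    return metrics_frame(rows)


def aggregate_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean and standard error per (program, scenario, design, cycle, pool),
    plus percent differences of gain and genomic accuracy versus the
    single-tester design where present."""
    frames = [t for t in tables if t is not None and len(t)]
    if not frames:
        raise ValueError("no replicate tables to aggregate")
    df = pd.concat(frames, ignore_index=True)
    keys = ["program", "scenario", "design", "cycle", "pool"]
    value_cols = [c for c in df.columns if c not in keys + ["replicate"]]
    g = df.groupby(keys)[value_cols]
    mean = g.mean()
    se = g.sem(ddof=1)
    out = mean.join(se, lsuffix="_mean", rsuffix="_se").reset_index()

    ref = out[out["design"] == "1t"][
        ["program", "scenario", "cycle", "pool", "gain_mean", "acc_genomic_mean"]
    ].rename(columns={"gain_mean": "_gain_1t", "acc_genomic_mean": "_acc_1t"})
    out = out.merge(ref, on=["program", "scenario", "cycle", "pool"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_gain_vs_1t"] = 100.0 * (out["gain_mean"] - out["_gain_1t"]) / out["_gain_1t"]
        out["pct_acc_vs_1t"] = 100.0 * (out["acc_genomic_mean"] - out["_acc_1t"]) / out["_acc_1t"]
    return out.drop(columns=["_gain_1t", "_acc_1t"])
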