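"""Synthetic cohort generator.

Emulates the statistical structure of a small resected-PDAC cohort treated
with adjuvant gemcitabine: log-normal tumor/normal fold changes for the four
gemcitabine-pathway genes (hENT1, CHOP, MRP1, DCK) with a Gaussian copula on
the log scale, Table-1-like clinical covariates, and survival times drawn from
a planted threshold tree with constant (exponential) hazard per leaf plus
uniform administrative censoring.

All randomness flows from a single integer seed through named substreams
(expression, clinical, survival — in that order), so a cohort is a pure
function of its :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PlantedLeaf",
    "SimulationConfig",
    "default_config",
    "config_from_yaml",
    "simulate_expression",
    "simulate_clinical",
    "simulate_survival",
    "assign_leaves",
    "make_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "GENES",
]

GENES = ("hENT1", "CHOP", "MRP1", "DCK")

# substream order (spawn keys off the master SeedSequence)
_SUB_EXPRESSION, _SUB_CLINICAL, _SUB_SURVIVAL = 0, 1, 2


@dataclass(frozen=True)
class PlantedLeaf:
    """A leaf of the planted hazard tree.

    ``rules`` is a conjunction of (variable, threshold, side) conditions,
    side "le" meaning value <= threshold and "gt" meaning value > threshold.
    The leaves of a config must partition the covariate space: every simulated
    patient must satisfy exactly one leaf's rule set.
    """

    name: str
    rules: tuple[tuple[str, float, str], ...]

    def contains(self, row) -> bool:
        for var, thr, side in self.rules:
            v = row[var]
            if side == "le":
                if not v <= thr:
                    return False
            elif side == "gt":
                if not v > thr:
                    return False
            else:
                raise ValueError(f"unknown rule side {side!r} (use 'le' or 'gt')")
        return True


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults are the study-like cohort."""

    n_patients: int
    genes: tuple[str, ...]
    gene_log_medians: dict[str, float]
    gene_log_sds: dict[str, float]
    gene_corr: np.ndarray  # same order as ``genes``; log-scale correlations
    planted_tree: tuple[PlantedLeaf, ...]
    leaf_hazards: dict[str, float]  # OS events per person-year, per leaf
    censor_time_max: float
    clinical: dict[str, tuple] = field(default_factory=dict)
    pfs_hazard_ratio: float = 58.0 / 35.0  # PFS vs OS hazard, per leaf
    # optional gene->clinical dependence: covariate -> (gene, logit slope per
    # SD of the gene's log expression); empty = independence
    clinical_gene_assoc: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        g = len(self.genes)
        corr = np.asarray(self.gene_corr, dtype=float)
        if corr.shape != (g, g):
            raise ValueError(f"gene_corr must be {g}x{g}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("gene_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("gene_corr must have unit diagonal")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError(
                f"gene_corr is not positive semi-definite (min eigenvalue {w.min():.3g})"
            )
        for gname in self.genes:
            if self.gene_log_sds[gname] < 0:
                raise ValueError(f"gene_log_sds[{gname!r}] must be >= 0")
        if not self.planted_tree:
            raise ValueError("planted_tree must have at least one leaf")
        for leaf in self.planted_tree:
            h = self.leaf_hazards.get(leaf.name)
            if h is None or h <= 0:
                raise ValueError(f"leaf_hazards[{leaf.name!r}] must be > 0")
        if self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be > 0")
        if self.pfs_hazard_ratio < 1.0:
            raise ValueError("pfs_hazard_ratio must be >= 1 (progression precedes death)")
        for name, spec in self.clinical.items():
            if spec[0] == "bernoulli" and not 0.0 <= spec[1] <= 1.0:
                raise ValueError(f"prevalence of {name!r} must be in [0,1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def default_config(n_patients: int = 26, seed: int = 0) -> SimulationConfig:
    """The stated cohort: 26 patients, published fold-change medians/IQRs,
    MRP1-hENT1 and MRP1-CHOP log-scale correlations, the mortality tree
    (DCK 0.27 then CHOP 0.25) with class rates 23/35/63 per 100 person-years,
    and Table-1 clinical prevalences."""

    def log_sd(q1: float, q3: float) -> float:
        # IQR of a log-normal: sd = (ln q3 - ln q1) / (2 * 0.6745)
        return (math.log(q3) - math.log(q1)) / (2 * 0.674489750196082)

    medians = {"hENT1": 0.53, "CHOP": 1.02, "MRP1": 0.58, "DCK": 1.15}
    iqrs = {
        "hENT1": (0.23, 0.94),
        "CHOP": (0.16, 2.02),
        "MRP1": (0.22, 1.21),
        "DCK": (0.28, 2.36),
    }
    corr = np.eye(4)
    idx = {g: i for i, g in enumerate(GENES)}
    for a, b, r in [("MRP1", "hENT1", 0.53), ("MRP1", "CHOP", 0.42)]:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    tree = (
        PlantedLeaf("low_risk", (("DCK", 0.27, "le"),)),
        PlantedLeaf("high_risk", (("DCK", 0.27, "gt"), ("CHOP", 0.25, "le"))),
        PlantedLeaf("mid_risk", (("DCK", 0.27, "gt"), ("CHOP", 0.25, "gt"))),
    )
    hazards = {"low_risk": 0.23, "mid_risk": 0.35, "high_risk": 0.63}
    clinical = {
        "jaundice": ("bernoulli", 0.58),
        "diabetes": ("bernoulli", 0.35),
        "family_history": ("bernoulli", 0.19),
        "previous_neoplasia": ("bernoulli", 0.08),
        "mucinous": ("bernoulli", 0.15),
        "margins_r1": ("bernoulli", 0.31),
        "stage_iib": ("bernoulli", 0.88),
        "vascular_invasion": ("bernoulli", 0.12),
        "node_positive": ("bernoulli", 0.88),
        "grading": ("categorical", (1, 2, 3), (0.20, 0.40, 0.40)),
        "lymph_node_ratio": ("beta", 1.0, 2.5),
        "cea_preop": ("lognormal", math.log(3.2), log_sd(2.0, 6.0)),
        "ca19_9_preop": ("lognormal", math.log(200.4), log_sd(53.5, 335.9)),
        "gem_cycles": ("poisson1", 4.3),
    }
    return SimulationConfig(
        n_patients=n_patients,
        genes=GENES,
        gene_log_medians={g: math.log(m) for g, m in medians.items()},
        gene_log_sds={g: log_sd(*iqrs[g]) for g in GENES},
        gene_corr=corr,
        planted_tree=tree,
        leaf_hazards=hazards,
        censor_time_max=6.0,
        clinical=clinical,
        seed=seed,
    )


def config_from_yaml(path, seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    Layout (unset sections fall back to the default config)::

        n_patients: 26
        censor_time_max: 6.0
        pfs_hazard_ratio: 1.657
        seed: 0
        genes:
          DCK: {log_median: 0.1398, log_sd: 1.5802}
          CHOP: {log_median: 0.0198, log_sd: 1.8797}
        correlations:            # list of [gene_a, gene_b, r]
          - [DCK, CHOP, 0.0]
        tree:                    # leaf name -> {rules: [[var, thr, le|gt]], hazard: per-year}
          ref:  {rules: [[DCK, 0.27, le]], hazard: 0.23}
          high: {rules: [[DCK, 0.27, gt], [CHOP, 0.25, le]], hazard: 2.07}
          mid:  {rules: [[DCK, 0.27, gt], [CHOP, 0.25, gt]], hazard: 0.69}
        clinical:                # covariate -> [kind, params...]
          jaundice: [bernoulli, 0.58]
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_config()
    if "genes" in raw:
        genes = tuple(raw["genes"])
        medians = {g: float(raw["genes"][g]["log_median"]) for g in genes}
        sds = {g: float(raw["genes"][g]["log_sd"]) for g in genes}
    else:
        genes, medians, sds = base.genes, base.gene_log_medians, base.gene_log_sds
    corr = np.eye(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for a, b, r in raw.get("correlations", []):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = float(r)
    if "genes" not in raw and "correlations" not in raw:
        corr = base.gene_corr
    if "tree" in raw:
        tree = tuple(
            PlantedLeaf(
                name,
                tuple((v, float(t), side) for v, t, side in leaf["rules"]),
            )
            for name, leaf in raw["tree"].items()
        )
        hazards = {name: float(leaf["hazard"]) for name, leaf in raw["tree"].items()}
    else:
        tree, hazards = base.planted_tree, base.leaf_hazards
    clinical = (
        {name: tuple(spec) for name, spec in raw["clinical"].items()}
        if "clinical" in raw
        else base.clinical
    )
    cfg = SimulationConfig(
        n_patients=int(raw.get("n_patients", base.n_patients)),
        genes=genes,
        gene_log_medians=medians,
        gene_log_sds=sds,
        gene_corr=corr,
        planted_tree=tree,
        leaf_hazards=hazards,
        censor_time_max=float(raw.get("censor_time_max", base.censor_time_max)),
        clinical=clinical,
        pfs_hazard_ratio=float(raw.get("pfs_hazard_ratio", base.pfs_hazard_ratio)),
        seed=int(raw.get("seed", base.seed)) if seed is None else int(seed),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Component simulators
# ---------------------------------------------------------------------------


def simulate_expression(config: SimulationConfig) -> pd.DataFrame:
    """Per-patient fold changes: exp of a correlated Gaussian draw on the log
    scale with the configured per-gene medians and SDs."""
    config.validate()
    rng = _substream(config.seed, _SUB_EXPRESSION)
    g = len(config.genes)
    corr = np.asarray(config.gene_corr, dtype=float)
    # eigen factor rather than Cholesky so exactly-singular PSD matrices work
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((config.n_patients, g)) @ factor.T
    mu = np.array([config.gene_log_medians[x] for x in config.genes])
    sd = np.array([config.gene_log_sds[x] for x in config.genes])
    log_fc = mu + sd * z
    return pd.DataFrame(np.exp(log_fc), columns=list(config.genes))


def simulate_clinical(config: SimulationConfig, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Clinical covariate columns: independent draws per configured covariate
    (Bernoulli / categorical / beta / log-normal / shifted Poisson), with an
    optional logit shift tying a binary covariate to a gene's log expression."""
    config.validate()
    rng = _substream(config.seed, _SUB_CLINICAL)
    n = config.n_patients
    cols = {}
    for name, spec in config.clinical.items():
        kind = spec[0]
        if kind == "bernoulli":
            p = np.full(n, float(spec[1]))
            assoc = config.clinical_gene_assoc.get(name)
            if assoc is not None:
                gene, slope = assoc
                if expression is None:
                    raise ValueError(
                        f"covariate {name!r} is gene-associated; expression required"
                    )
                z = np.log(expression[gene].to_numpy(dtype=float))
                z = (z - config.gene_log_medians[gene]) / max(config.gene_log_sds[gene], 1e-12)
                with np.errstate(over="ignore"):
                    logit = np.log(p / (1 - p)) + slope * z
                p = 1.0 / (1.0 + np.exp(-logit))
            cols[name] = (rng.random(n) < p).astype(int)
        elif kind == "categorical":
            levels, probs = spec[1], np.asarray(spec[2], dtype=float)
            cols[name] = rng.choice(np.asarray(levels), size=n, p=probs / probs.sum())
        elif kind == "beta":
            cols[name] = rng.beta(spec[1], spec[2], size=n)
        elif kind == "lognormal":
            cols[name] = np.exp(spec[1] + spec[2] * rng.standard_normal(n))
        elif kind == "poisson1":
            cols[name] = 1 + rng.poisson(spec[1], size=n)
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
    return pd.DataFrame(cols)


def assign_leaves(rows: pd.DataFrame, planted_tree: tuple[PlantedLeaf, ...]) -> np.ndarray:
    """Map each row to its planted leaf; a row matching zero or several leaves
    is a config error and is reported by row label."""
    names = np.empty(len(rows), dtype=object)
    for i, (label, row) in enumerate(rows.iterrows()):
        hits = [leaf.name for leaf in planted_tree if leaf.contains(row)]
        if len(hits) != 1:
            raise ValueError(
                f"row {label!r} matches {len(hits)} planted leaves ({hits}); "
                "the planted tree must partition the covariate space"
            )
        names[i] = hits[0]
    return names


def simulate_survival(
    rows: pd.DataFrame,
    planted_tree: tuple[PlantedLeaf, ...],
    leaf_hazards: dict[str, float],
    censor_time_max: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One endpoint's (time, event) per row: event time exponential at the
    row's leaf hazard, censoring uniform on (0, censor_time_max]."""
    leaves = assign_leaves(rows, planted_tree)
    lam = np.array([leaf_hazards[name] for name in leaves], dtype=float)
    rng = _substream(seed, _SUB_SURVIVAL)
    t_event = rng.exponential(1.0 / lam)
    censor = (1.0 - rng.random(len(rows))) * censor_time_max  # in (0, cmax]
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return time, event


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def make_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Compose the three simulators into a cohort table.

    OS death times are exponential at the leaf hazard; progression is a
    competing exponential with rate (pfs_hazard_ratio - 1) * leaf hazard so
    that the PFS hazard per leaf is exactly pfs_hazard_ratio * OS hazard and
    progression never follows death (pfs_time <= os_time). One administrative
    censoring time per patient is shared by both endpoints.
    """
    config.validate()
    expr = simulate_expression(config)
    clin = simulate_clinical(config, expression=expr)
    covars = pd.concat([expr, clin], axis=1)
    leaves = assign_leaves(covars, config.planted_tree)
    lam_os = np.array([config.leaf_hazards[name] for name in leaves], dtype=float)
    lam_extra = (config.pfs_hazard_ratio - 1.0) * lam_os

    rng = _substream(config.seed, _SUB_SURVIVAL)
    n = config.n_patients
    t_death = rng.exponential(1.0 / lam_os)
    if np.all(lam_extra <= 0):
        t_prog = t_death.copy()
    else:
        with np.errstate(divide="ignore"):
            extra = rng.exponential(np.where(lam_extra > 0, 1.0 / np.maximum(lam_extra, 1e-300), np.inf))
        t_prog = np.minimum(extra, t_death)
    censor = (1.0 - rng.random(n)) * config.censor_time_max

    out = pd.DataFrame({"patient_id": [f"P{i + 1:03d}" for i in range(n)]})
    for gene in config.genes:
        out[f"{gene}_fc"] = expr[gene].to_numpy()
    for col in clin.columns:
        out[col] = clin[col].to_numpy()
    out["os_time"] = np.minimum(t_death, censor)
    out["os_event"] = (t_death <= censor).astype(int)
    out["pfs_time"] = np.minimum(t_prog, censor)
    out["pfs_event"] = (t_prog <= censor).astype(int)
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """UTF-8, decimal-point, newline-terminated CSV; floats round-trip exactly."""
    cohort.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
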