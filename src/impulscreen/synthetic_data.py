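"""Synthetic stand-ins for the study's raw data, with machine-readable truth.

Two generators:

* :func:`make_expression_dataset` emulates a cortical single-cell CPM matrix
  with the composition of the mouse anterior cingulate reference data: ~10
  clusters spanning glutamatergic layers (including an L4/5-IT target
  cluster of ~1238 cells), GABAergic and non-neuronal classes, a
  reporter-positive subset of 676 glutamatergic cells of which 502 overlap
  the L4/5-IT cluster, a level-3 contrast pool of 3514 cells and 5190 cells
  in total.  A curated list of GPCR genes (402 by default) is annotated with
  coupling classes, and chosen markers are planted with a controlled
  mean-expression fold and per-set detection fractions.

* :func:`make_cohort` simulates an operant cohort — groups of subjects, each
  run under vehicle and a drug condition with known multiplicative effects
  and log-normal subject-level random effects — producing the event logs the
  scoring pipeline consumes plus the realised per-subject parameters.

Expression noise is a log-normal expressed-value layer under Bernoulli
dropout: the screen consumes CPM, so read-depth/count modelling adds nothing
the statistics would see.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .io_formats import ExpressionDataset
from .task_engine import (
    CHALLENGE_PRESETS,
    AgentParams,
    ChallengeSpec,
    SimulatedSession,
    classify_trials,
    session_metrics,
    simulate_session,
)

__all__ = [
    "ClusterSpec",
    "PlantedMarker",
    "ExpressionSimConfig",
    "SimulatedExpression",
    "make_expression_dataset",
    "GroupSpec",
    "CohortSimConfig",
    "SimulatedCohort",
    "make_cohort",
]

#: Detection threshold the planted detection fractions are calibrated to.
DETECTION_THRESHOLD = 1.0


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    cell_class: str  # glutamatergic | GABAergic | non-neuronal
    n: int


# Default roster mirroring the reference dataset's composition: the L4/5-IT
# target cluster (1238 cells), a level-3 contrast pool of 3514 cells
# (GABAergic 1200 + non-neuronal 400 + L6 1014 + L2/3 900), and an L5-PT
# cluster outside both pools, totalling 5190 cells.
DEFAULT_CLUSTERS: tuple[ClusterSpec, ...] = (
    ClusterSpec("L2/3 IT", "glutamatergic", 900),
    ClusterSpec("L4/5 IT", "glutamatergic", 1238),
    ClusterSpec("L5 PT", "glutamatergic", 438),
    ClusterSpec("L6 IT", "glutamatergic", 600),
    ClusterSpec("L6 CT", "glutamatergic", 414),
    ClusterSpec("Pvalb", "GABAergic", 500),
    ClusterSpec("Sst", "GABAergic", 400),
    ClusterSpec("Vip", "GABAergic", 300),
    ClusterSpec("Astro", "non-neuronal", 250),
    ClusterSpec("Oligo", "non-neuronal", 150),
)

#: Reporter-positive glutamatergic cells per cluster: 502 inside L4/5-IT plus
#: 174 in L5-PT gives the 676-cell reporter pull with 502 cells in both sets.
DEFAULT_REPORTER_COUNTS: dict[str, int] = {"L4/5 IT": 502, "L5 PT": 174}


@dataclass(frozen=True)
class PlantedMarker:
    """A gene planted with a known target-versus-contrast expression profile.

    ``fold`` is the intended ratio of per-set mean CPM (target over
    contrast); ``pct_t``/``pct_c`` the intended detection fractions at
    CPM >= 1 in target and non-target cells.
    """

    gene: str
    coupling: str = "Gi"
    fold: float = 10.0
    pct_t: float = 0.9
    pct_c: float = 0.05
    is_gpcr: bool = True


@dataclass(frozen=True)
class ExpressionSimConfig:
    clusters: tuple[ClusterSpec, ...] = DEFAULT_CLUSTERS
    reporter_counts: dict = field(default_factory=lambda: dict(DEFAULT_REPORTER_COUNTS))
    n_genes: int = 20000
    n_gpcr: int = 402
    n_sensory_gpcr: int = 3
    planted: tuple[PlantedMarker, ...] = ()
    #: log-normal hyper-prior on per-gene mean expressed CPM
    mean_cpm_log_mu: float = math.log(20.0)
    mean_cpm_log_sigma: float = 1.0
    #: per-gene detection probability range (Bernoulli dropout)
    detect_low: float = 0.05
    detect_high: float = 0.6
    #: within-gene log-normal sigma of expressed values
    value_sigma: float = 0.5
    #: mean expressed CPM of planted markers in contrast cells
    planted_contrast_level: float = 20.0
    region: str = "ACA"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c.n <= 0 for c in self.clusters):
            raise ConfigurationError("cluster cell counts must be > 0")
        if self.n_gpcr + len(self.planted) > self.n_genes:
            raise ConfigurationError("more GPCR genes than genes in total")
        for m in self.planted:
            if m.fold <= 0:
                raise ConfigurationError(f"{m.gene}: fold must be > 0")
            if not (0 < m.pct_t <= 1 and 0 <= m.pct_c <= 1):
                raise ConfigurationError(f"{m.gene}: detection fractions out of range")
        cluster_names = {c.name for c in self.clusters}
        unknown = set(self.reporter_counts) - cluster_names
        if unknown:
            raise ConfigurationError(f"reporter counts for unknown clusters {unknown}")

    def scaled(self, factor: float, n_genes: int | None = None) -> "ExpressionSimConfig":
        """A proportionally smaller roster (cluster sizes scaled, >= 4 cells)."""
        clusters = tuple(
            replace(c, n=max(4, int(round(c.n * factor)))) for c in self.clusters
        )
        sizes = {c.name: c.n for c in clusters}
        reporters = {
            k: min(sizes[k], max(2, int(round(v * factor))))
            for k, v in self.reporter_counts.items()
        }
        return replace(
            self,
            clusters=clusters,
            reporter_counts=reporters,
            n_genes=n_genes if n_genes is not None else self.n_genes,
        )


@dataclass
class SimulatedExpression:
    dataset: ExpressionDataset
    cell_annotation: pd.DataFrame
    gene_annotation: pd.DataFrame
    truth: pd.DataFrame  # one row per planted marker


def _gene_names(cfg: ExpressionSimConfig) -> tuple[list[str], list[str]]:
    planted_names = [m.gene for m in cfg.planted]
    gpcr = [f"Gpr{i:03d}" for i in range(cfg.n_gpcr - len(planted_names))]
    gpcr_all = planted_names + gpcr
    n_bg = cfg.n_genes - len(gpcr_all)
    background = [f"Gene{i:05d}" for i in range(n_bg)]
    return gpcr_all, background


def make_expression_dataset(cfg: ExpressionSimConfig) -> SimulatedExpression:
    """Generate the expression matrix, annotations and planted-marker truth."""
    rng = np.random.default_rng(cfg.seed)

    # --- cells -------------------------------------------------------------
    cell_ids: list[str] = []
    classes: list[str] = []
    clusters: list[str] = []
    reporter: list[bool] = []
    for c in cfg.clusters:
        n_rep = cfg.reporter_counts.get(c.name, 0)
        if n_rep > c.n:
            raise ConfigurationError(
                f"cluster {c.name}: {n_rep} reporter cells exceed cluster size {c.n}"
            )
        slug = c.name.replace("/", "").replace(" ", "_")
        for i in range(c.n):
            cell_ids.append(f"{slug}.{i:04d}")
            classes.append(c.cell_class)
            clusters.append(c.name)
            reporter.append(i < n_rep and c.cell_class == "glutamatergic")
    cells = pd.DataFrame(
        {
            "cell_class": classes,
            "cluster": clusters,
            "reporter_positive": reporter,
            "region": cfg.region,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    n_cells = len(cells)

    # target pool for planting: L4/5-IT cluster union reporter pull, so a
    # marker is selective under both target definitions
    target_mask = (
        (cells["cluster"] == "L4/5 IT") | cells["reporter_positive"]
    ).to_numpy()

    # --- genes -------------------------------------------------------------
    gpcr_names, bg_names = _gene_names(cfg)
    gene_ids = np.asarray(gpcr_names + bg_names, dtype=object)
    n_genes = len(gene_ids)
    planted_idx = {m.gene: i for i, m in enumerate(cfg.planted)}

    is_gpcr = np.zeros(n_genes, dtype=bool)
    is_gpcr[: len(gpcr_names)] = True
    coupling = np.asarray(["unknown"] * n_genes, dtype=object)
    coupling[: len(gpcr_names)] = rng.choice(
        ["Gi", "Gq", "Gs", "other"], size=len(gpcr_names), p=[0.3, 0.3, 0.2, 0.2]
    )
    for m in cfg.planted:
        coupling[planted_idx[m.gene]] = m.coupling
        is_gpcr[planted_idx[m.gene]] = m.is_gpcr
    is_sensory = np.zeros(n_genes, dtype=bool)
    n_planted = len(cfg.planted)
    sensory_pool = np.arange(n_planted, len(gpcr_names))
    if cfg.n_sensory_gpcr and len(sensory_pool):
        chosen = rng.choice(
            sensory_pool, size=min(cfg.n_sensory_gpcr, len(sensory_pool)), replace=False
        )
        is_sensory[chosen] = True
    genes = pd.DataFrame(
        {"is_gpcr": is_gpcr, "coupling": coupling, "is_sensory": is_sensory},
        index=pd.Index(gene_ids, name="gene"),
    )

    # --- matrix ------------------------------------------------------------
    mean_cpm = rng.lognormal(cfg.mean_cpm_log_mu, cfg.mean_cpm_log_sigma, size=n_genes)
    detect_p = rng.uniform(cfg.detect_low, cfg.detect_high, size=n_genes)
    # mean of the expressed-value distribution so that overall mean is mean_cpm
    sig = cfg.value_sigma

    # planted rows are drawn first so their statistics are controlled exactly
    planted_rows: dict[int, np.ndarray] = {}
    truth_rows = []
    for m in cfg.planted:
        gi = planted_idx[m.gene]
        contrast_expressed_mean = cfg.planted_contrast_level / max(m.pct_c, 1e-9)
        target_expressed_mean = m.fold * cfg.planted_contrast_level / m.pct_t
        for label, mean_v in (
            ("contrast", contrast_expressed_mean),
            ("target", target_expressed_mean),
        ):
            if mean_v < 2.0 * DETECTION_THRESHOLD:
                raise ConfigurationError(
                    f"{m.gene}: requested pct/fold combination puts the {label} "
                    f"expressed mean at {mean_v:.2f} CPM, too close to the "
                    f"detection threshold to realise the detection fraction"
                )
        row = np.zeros(n_cells)
        for mask, pct, mean_v in (
            (target_mask, m.pct_t, target_expressed_mean),
            (~target_mask, m.pct_c, contrast_expressed_mean),
        ):
            n_set = int(mask.sum())
            # exact detection counts (rounded), so the requested fractions —
            # and through them the planted fold — are realised tightly
            n_det = int(round(pct * n_set))
            detected = np.zeros(n_set, dtype=bool)
            detected[rng.permutation(n_set)[:n_det]] = True
            mu = math.log(mean_v) - sig**2 / 2.0
            vals = rng.lognormal(mu, sig, size=n_set)
            row[mask] = np.where(detected, vals, 0.0)
        planted_rows[gi] = row
        truth_rows.append(
            dict(
                gene=m.gene,
                coupling=m.coupling,
                is_gpcr=m.is_gpcr,
                fold=m.fold,
                pct_t=m.pct_t,
                pct_c=m.pct_c,
                n_target_cells=int(target_mask.sum()),
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "coupling", "is_gpcr", "fold", "pct_t", "pct_c", "n_target_cells"],
    )

    blocks = []
    chunk = max(1, int(2e7 // max(n_cells, 1)))
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        g = stop - start
        detected = rng.random((g, n_cells)) < detect_p[start:stop, None]
        expressed_mean = mean_cpm[start:stop] / detect_p[start:stop]
        mu = np.log(expressed_mean) - sig**2 / 2.0
        vals = rng.lognormal(mu[:, None], sig, size=(g, n_cells))
        dense = np.where(detected, vals, 0.0)
        for gi, row in planted_rows.items():
            if start <= gi < stop:
                dense[gi - start] = row
        blocks.append(sp.csr_matrix(dense))
    matrix = sp.vstack(blocks).tocsr() if blocks else sp.csr_matrix((0, n_cells))

    ds = ExpressionDataset(matrix, gene_ids, np.asarray(cell_ids, dtype=object))
    return SimulatedExpression(ds, cells, genes, truth)


# ---------------------------------------------------------------------------
# Behavioural cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: its size and the agent its subjects vary around.

    The agent's ``drug_multipliers`` must contain every non-vehicle condition
    the cohort is run under (e.g. ``{"cno": {"premature_hazard": 0.3}}`` for
    a Gi-like anti-impulsive effect; a control group uses factor 1).
    """

    name: str
    n_subjects: int
    agent: AgentParams

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError(f"group {self.name!r}: need >= 2 subjects")


@dataclass(frozen=True)
class CohortSimConfig:
    groups: tuple[GroupSpec, ...]
    challenge: str = "fiti9"
    conditions: tuple[str, ...] = ("vehicle", "cno")
    subject_sigma: float = 0.25  # log-normal sd of subject random effects
    seed: int = 0

    def __post_init__(self) -> None:
        if "vehicle" not in self.conditions:
            raise ConfigurationError("conditions must include 'vehicle'")
        if self.challenge not in CHALLENGE_PRESETS:
            raise ConfigurationError(
                f"unknown challenge {self.challenge!r}; "
                f"known: {sorted(CHALLENGE_PRESETS)}"
            )


@dataclass
class SimulatedCohort:
    spec: ChallengeSpec
    sessions: dict  # (subject, condition) -> SimulatedSession
    truth: pd.DataFrame  # realised per-subject parameters

    def metrics_table(self, use_classifier: bool = True) -> pd.DataFrame:
        """Per subject x condition session metrics, long format.

        With ``use_classifier`` the event logs are re-scored through
        :func:`impulscreen.task_engine.classify_trials` (the end-to-end
        path); otherwise the simulator's ground-truth trials are summarised
        directly.
        """
        rows = []
        meta = self.truth.set_index("subject")
        for (subject, condition), sim in self.sessions.items():
            trials = (
                classify_trials(sim.log, self.spec).trials
                if use_classifier
                else sim.truth
            )
            m = session_metrics(trials).as_dict()
            rows.append(
                dict(subject=subject, group=meta.loc[subject, "group"],
                     condition=condition, **m)
            )
        return pd.DataFrame(rows)


def make_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Simulate every subject of every group under every condition.

    Subject-level heterogeneity is a log-normal perturbation (sigma
    ``cfg.subject_sigma``) of the group agent's premature hazard and latency
    medians, applied once per subject so it cancels in within-subject
    ratios only to the extent the true drug effect is multiplicative.
    """
    spec = CHALLENGE_PRESETS[cfg.challenge]
    root = np.random.SeedSequence(cfg.seed)
    sessions: dict[tuple[str, str], SimulatedSession] = {}
    truth_rows = []
    streams = root.spawn(sum(g.n_subjects for g in cfg.groups))
    k = 0
    for group in cfg.groups:
        for cond in cfg.conditions:
            if cond != "vehicle" and cond not in group.agent.drug_multipliers:
                raise ConfigurationError(
                    f"group {group.name!r}: condition {cond!r} has no multipliers"
                )
        for s in range(group.n_subjects):
            subject = f"{group.name}.s{s:02d}"
            rng = np.random.default_rng(streams[k])
            k += 1
            re_hazard = float(np.exp(rng.normal(0.0, cfg.subject_sigma)))
            re_lat = float(np.exp(rng.normal(0.0, cfg.subject_sigma)))
            agent = replace(
                group.agent,
                premature_hazard=group.agent.premature_hazard * re_hazard,
                response_latency_median=group.agent.response_latency_median * re_lat,
                reward_latency_median=group.agent.reward_latency_median * re_lat,
            )
            truth_rows.append(
                dict(
                    subject=subject,
                    group=group.name,
                    premature_hazard=agent.premature_hazard,
                    response_latency_median=agent.response_latency_median,
                    reward_latency_median=agent.reward_latency_median,
                    **{
                        f"mult_{cond}_{key}": val
                        for cond, m in group.agent.drug_multipliers.items()
                        for key, val in m.items()
                    },
                )
            )
            for cond in cfg.conditions:
                sessions[(subject, cond)] = simulate_session(
                    spec, agent, condition=cond, seed=rng
                )
    return SimulatedCohort(spec, sessions, pd.DataFrame(truth_rows))
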