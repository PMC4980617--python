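"""Protocol orchestration: initialisation, equilibration, forcing, ensembles.

A run proceeds in three stages.  (i) Initialisation: the small-world
substrate and background proximity are drawn, degree preferences and
dispositions sampled, behaviour set by the Heaviside rule, and the initial
contact network built from a fully connected interaction network.  (ii) The
system equilibrates for ``equilibration_steps`` under the fully coupled
dynamics with the disposition distribution held fixed.  (iii) For
``forcing_steps`` the disposition distribution is dragged from bimodal to
quasi-unimodal while the selected variant's dynamics run:

* ``coupled``     — full model (steps 1-6);
* ``interaction`` — local influence on a frozen contact network (no step 5);
* ``network``     — behaviour tracks the disposition threshold, no peer term;
* ``mean_field``  — peer field replaced by global prevalence S/N.

All variants share the equilibrated coupled state as their starting point,
and variants run with the same seed consume identical substrate, background
proximity and disposition-forcing realisations (named RNG substreams), so
cross-variant differences are attributable to the dynamics alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from ._graphs import to_graph
from .contacts import initial_contact_network, proximity_matrix, update_contact_network
from .errors import ConfigurationError, InternalModelError
from .forcing import (
    ForcingNoiseParams,
    ParabolicDensity,
    evolve_dispositions,
    linear_forcing_schedule,
    sample_initial_dispositions,
)
from .influence import (
    VARIANTS,
    AgentPopulation,
    InfluenceParams,
    initialise_behaviour,
    sample_degree_preferences,
    update_behaviours,
)
from .interaction import (
    InteractionParams,
    interaction_probabilities,
    sample_interaction_network,
    shortest_path_distances,
)
from .metrics import (
    bootstrap_bands,
    conditional_smoking_probability,
    eigenvector_centrality,
    prevalence,
)
from .rng import Stream, stream_rng, stream_seed
from .substrate import SubstrateParams, build_background_proximity, generate_ws_network

ALL_METRICS = ("prevalence", "evc", "cp")


@dataclass(frozen=True)
class RunConfig:
    """Full parameterisation of one simulation scenario."""

    n_agents: int = 500
    # substrate / background proximity
    mean_degree: int = 10
    rewiring_prob: float = 0.03
    distance_decrement: float = 0.25
    noise_amplitude: float = 0.1
    proximity_floor: float = 0.2
    # interaction layer
    beta: float = 0.8
    epsilon: float = 0.03
    delta: float = 2.0
    # behaviour influence
    switch_scale: float = 0.1
    variant: str = "coupled"
    # proximity mixture and degree preferences
    alpha: float = 0.2
    degree_pref_mean: float = 10.0
    degree_pref_sd: float = 3.0
    # disposition forcing
    c1: float = 2.5
    c_final: float = 0.25
    forcing_step_scale: float = 0.05
    forcing_log_sd: float = 0.5
    ks_alpha: float = 0.10
    max_inner_iterations: int = 500
    # protocol
    equilibration_steps: int = 200
    forcing_steps: int = 1000
    ensemble_size: int = 20
    base_seed: int = 0
    # outputs
    metrics: tuple[str, ...] = ALL_METRICS
    cp_max_distance: int = 5
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.equilibration_steps < 0 or self.forcing_steps < 0:
            raise ConfigurationError("step counts must be nonnegative")
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ConfigurationError(f"unknown metrics {sorted(unknown)}")
        # component params validate their own fields eagerly
        self.substrate_params(seed=0)
        self.interaction_params()
        self.influence_params()
        self.noise_params()

    # -- component parameter views ------------------------------------------
    def substrate_params(self, seed: int) -> SubstrateParams:
        return SubstrateParams(self.n_agents, self.mean_degree, self.rewiring_prob, seed)

    def interaction_params(self) -> InteractionParams:
        return InteractionParams(self.beta, self.epsilon, self.delta)

    def influence_params(self, variant: str | None = None) -> InfluenceParams:
        return InfluenceParams(self.switch_scale, variant or self.variant)

    def noise_params(self) -> ForcingNoiseParams:
        return ForcingNoiseParams(
            self.forcing_step_scale, self.forcing_log_sd, self.ks_alpha, self.max_inner_iterations
        )

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Trajectory:
    """Per-step metric series of a single run, with provenance."""

    metrics: pd.DataFrame
    seed: int
    variant: str
    config: RunConfig
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def provenance(self) -> dict:
        return {
            "config_digest": self.config.digest(),
            "seed": self.seed,
            "variant": self.variant,
            "n_steps": int(len(self.metrics)),
            "package_version": _pkg_version,
        }

    def save(self, directory) -> None:
        """Write metrics.csv, config.yaml, provenance.json and any contact
        snapshots (edge list + GraphML) into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(directory / "metrics.csv", index=False)
        self.config.to_yaml(directory / "config.yaml")
        with open(directory / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        for step, adj in self.snapshots.items():
            g = to_graph(adj)
            nx.write_edgelist(g, directory / f"contact_{step:05d}.edgelist", data=False)
            nx.write_graphml(g, directory / f"contact_{step:05d}.graphml")

    @classmethod
    def load(cls, directory) -> "Trajectory":
        directory = Path(directory)
        metrics = pd.read_csv(directory / "metrics.csv")
        config = RunConfig.from_yaml(directory / "config.yaml")
        with open(directory / "provenance.json") as fh:
            prov = json.load(fh)
        snapshots = {}
        for path in sorted(directory.glob("contact_*.edgelist")):
            step = int(path.stem.split("_")[1])
            g = nx.read_edgelist(path, nodetype=int)
            g.add_nodes_from(range(config.n_agents))
            snapshots[step] = nx.to_numpy_array(g, nodelist=range(config.n_agents), dtype=bool)
        return cls(metrics, prov["seed"], prov["variant"], config, snapshots)


@dataclass
class EnsembleSummary:
    """Across-run means with bootstrap confidence bands.

    ``series``: per-step across-run mean of each metric (wide format).
    ``bands``: long format with lo/hi at 95% and 99%, sharing one resample
    set so the 99% band always contains the 95% band.
    """

    series: pd.DataFrame
    bands: pd.DataFrame
    seeds: list[int]
    variant: str
    config: RunConfig
    runs: list[Trajectory] | None = None
    failures: list[int] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.seeds)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(directory / "ensemble_series.csv", index=False)
        self.bands.to_csv(directory / "ensemble_bands.csv", index=False)
        self.config.to_yaml(directory / "config.yaml")
        with open(directory / "ensemble.json", "w") as fh:
            json.dump(
                {
                    "variant": self.variant,
                    "seeds": self.seeds,
                    "failures": self.failures,
                    "config_digest": self.config.digest(),
                    "package_version": _pkg_version,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _metric_columns(config: RunConfig) -> list[str]:
    cols = []
    if "prevalence" in config.metrics:
        cols.append("prevalence")
    if "evc" in config.metrics:
        cols += ["evc_smokers", "evc_nonsmokers"]
    if "cp" in config.metrics:
        cols += [f"cp_d{d}" for d in range(1, config.cp_max_distance + 1)]
    return cols


def run_simulation(config: RunConfig, seed: int) -> Trajectory:
    """Execute the full protocol for one seed; bit-reproducible."""
    n = config.n_agents
    variant = config.variant

    substrate = generate_ws_network(config.substrate_params(stream_seed(seed, Stream.SUBSTRATE)))
    background = build_background_proximity(
        substrate,
        decrement=config.distance_decrement,
        noise_amp=config.noise_amplitude,
        floor=config.proximity_floor,
        seed=stream_seed(seed, Stream.BACKGROUND),
    )
    q = sample_degree_preferences(
        n, config.degree_pref_mean, config.degree_pref_sd,
        stream_rng(seed, Stream.DEGREE_PREFERENCE),
    )
    density0 = ParabolicDensity.from_endpoint_values(config.c1, config.c1)
    gamma = sample_initial_dispositions(n, density0, stream_rng(seed, Stream.DISPOSITION))
    pop = AgentPopulation(q, gamma, initialise_behaviour(gamma))

    prox = proximity_matrix(background, pop.smoking_state, config.alpha)
    contact = initial_contact_network(prox, q)
    dist = shortest_path_distances(contact)

    iparams = config.interaction_params()
    noise = config.noise_params()
    schedule = linear_forcing_schedule(config.c1, config.c_final, config.forcing_steps)

    rng_interaction = stream_rng(seed, Stream.INTERACTION)
    rng_switch = stream_rng(seed, Stream.SWITCHING)
    rng_forcing = stream_rng(seed, Stream.FORCING)

    coupled_influence = config.influence_params("coupled")
    variant_influence = config.influence_params(variant)

    total = config.equilibration_steps + config.forcing_steps
    columns = _metric_columns(config)
    records = np.empty((total, len(columns)))
    phases = []
    snapshots: dict[int, np.ndarray] = {}
    pi = interaction_probabilities(dist, iparams)
    contact_frozen = False

    for t in range(1, total + 1):
        forcing = t > config.equilibration_steps
        # Step 1: interaction probabilities from G^C(t-1) distances
        if not contact_frozen:
            pi = interaction_probabilities(dist, iparams)
        # Step 2: sample the interaction network
        inter = sample_interaction_network(pi, rng_interaction)
        # Step 3: behaviour update (coupled dynamics during equilibration)
        influence = variant_influence if forcing else coupled_influence
        pop = update_behaviours(pop, inter, influence, rng_switch)
        # Step 4: proximity matrix from current behaviour
        prox = proximity_matrix(background, pop.smoking_state, config.alpha)
        # Step 5: contact-network update (frozen for the interaction variant
        # once forcing starts)
        if forcing and variant == "interaction":
            contact_frozen = True
        else:
            contact = update_contact_network(contact, inter, prox, q)
            dist = shortest_path_distances(contact)
            degrees = contact.sum(axis=1)
            if np.any(degrees > q):
                raise InternalModelError(f"degree bound violated at step {t}")
        # Step 6: external forcing of the disposition distribution
        if forcing:
            c2 = schedule[t - config.equilibration_steps - 1]
            target = ParabolicDensity.from_endpoint_values(config.c1, c2)
            gamma = evolve_dispositions(pop.disposition, target, noise, rng_forcing)
            pop = dataclasses.replace(pop, disposition=gamma)

        # record observables of the post-update state
        row = []
        states = pop.smoking_state
        if "prevalence" in config.metrics:
            row.append(prevalence(states))
        if "evc" in config.metrics:
            evc = eigenvector_centrality(contact)
            smokers = states == 1
            row.append(float(evc[smokers].mean()) if smokers.any() else np.nan)
            row.append(float(evc[~smokers].mean()) if (~smokers).any() else np.nan)
        if "cp" in config.metrics:
            for d in range(1, config.cp_max_distance + 1):
                row.append(conditional_smoking_probability(dist, states, d))
        records[t - 1] = row
        phases.append("forcing" if forcing else "equilibration")
        if config.snapshot_every and t % config.snapshot_every == 0:
            snapshots[t] = contact.copy()

    frame = pd.DataFrame(records, columns=columns)
    frame.insert(0, "step", np.arange(1, total + 1))
    frame.insert(1, "phase", phases)
    return Trajectory(frame, seed, variant, config, snapshots)


def run_ensemble(
    config: RunConfig,
    n_runs: int | None = None,
    base_seed: int | None = None,
    keep_runs: bool = False,
    bootstrap_reps: int = 2000,
) -> EnsembleSummary:
    """Run ``n_runs`` independent realisations (seeds ``base_seed + k``) and
    aggregate per-step metrics with bootstrapped 95%/99% bands.

    Runs share nothing but the configuration; each redraws the substrate,
    background proximity and dispositions from its own seed.  A failed run is
    recorded in ``failures`` and excluded from the aggregates.
    """
    n_runs = config.ensemble_size if n_runs is None else n_runs
    base_seed = config.base_seed if base_seed is None else base_seed
    seeds, runs, failures = [], [], []
    for k in range(n_runs):
        seed = base_seed + k
        try:
            runs.append(run_simulation(config, seed))
            seeds.append(seed)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"run with seed {seed} failed: {exc}")
            failures.append(seed)
    if not runs:
        raise InternalModelError("all ensemble runs failed")

    columns = _metric_columns(config)
    steps = runs[0].metrics["step"].to_numpy()
    rng_boot = stream_rng(base_seed, Stream.BOOTSTRAP)
    series = {"step": steps, "phase": runs[0].metrics["phase"].to_numpy()}
    band_rows = []
    for col in columns:
        matrix = np.stack([r.metrics[col].to_numpy() for r in runs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            series[col] = np.nanmean(matrix, axis=0)
            series[f"{col}_nruns"] = np.isfinite(matrix).sum(axis=0)
            bands = bootstrap_bands(matrix, (0.95, 0.99), bootstrap_reps, rng_boot)
        for level, (lo, hi) in bands.items():
            band_rows.append(
                pd.DataFrame(
                    {"step": steps, "metric": col, "level": level, "lo": lo, "hi": hi}
                )
            )
    return EnsembleSummary(
        series=pd.DataFrame(series),
        bands=pd.concat(band_rows, ignore_index=True),
        seeds=seeds,
        variant=config.variant,
        config=config,
        runs=runs if keep_runs else None,
        failures=failures,
    )


def transition_stats(
    traj: Trajectory, onset_window: int = 25, final_window: int = 50
) -> dict[str, float]:
    """Per-run transition summary relative to the forcing-onset baseline.

    Baselines average the last ``onset_window`` equilibration steps; final
    values average the last ``final_window`` steps.  EVC entries are reported
    as final/baseline ratios, CP entries as relative changes
    ``(final - baseline) / baseline`` (the normalise-then-average convention:
    normalisation happens inside each run before any cross-run averaging).
    """
    m = traj.metrics
    eq = traj.config.equilibration_steps
    onset = m[(m["step"] > eq - onset_window) & (m["step"] <= eq)]
    final = m[m["step"] > m["step"].max() - final_window]
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if "prevalence" in m.columns:
            onset_row = m.loc[m["step"] == eq, "prevalence"]
            out["prevalence_onset"] = float(
                onset_row.iloc[0] if len(onset_row) else m["prevalence"].iloc[0]
            )
            out["prevalence_final"] = float(final["prevalence"].mean())
            out["prevalence_drop"] = out["prevalence_onset"] - out["prevalence_final"]
        for col in m.columns:
            if col.startswith("evc_"):
                base = np.nanmean(onset[col].to_numpy())
                out[f"{col}_rel_final"] = float(np.nanmean(final[col].to_numpy()) / base)
            if col.startswith("cp_d"):
                base = np.nanmean(onset[col].to_numpy())
                out[f"{col}_rel_change"] = float(
                    (np.nanmean(final[col].to_numpy()) - base) / base
                )
    return out


@dataclass
class VariantComparison:
    """Aligned ensembles of several variants plus a per-variant report."""

    report: pd.DataFrame
    summaries: dict[str, EnsembleSummary]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(directory / "variant_report.csv")
        for variant, summary in self.summaries.items():
            summary.save(directory / variant)


def compare_variants(
    config: RunConfig,
    variants: tuple[str, ...] = VARIANTS,
    n_runs: int | None = None,
    base_seed: int | None = None,
    keep_runs: bool = False,
) -> VariantComparison:
    """Run aligned ensembles for several variants.

    Run index ``k`` uses seed ``base_seed + k`` in every variant, so the
    substrate, background proximity, degree preferences and the disposition
    forcing path are identical across variants and only the dynamics differ.
    The report aggregates per-run transition statistics per variant.
    """
    if len(variants) < 1:
        raise ConfigurationError("need at least one variant")
    summaries: dict[str, EnsembleSummary] = {}
    rows = {}
    for variant in variants:
        cfg = dataclasses.replace(config, variant=variant)
        summary = run_ensemble(cfg, n_runs=n_runs, base_seed=base_seed, keep_runs=True)
        stats = pd.DataFrame([transition_stats(r) for r in summary.runs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[variant] = stats.mean(skipna=True)
        if not keep_runs:
            summary.runs = None
        summaries[variant] = summary
    report = pd.DataFrame(rows).T
    report.index.name = "variant"
    return VariantComparison(report=report, summaries=summaries)
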