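"""Synthetic study generator with known ground truth.

Emulates the shape of a three-group mouse gut-microbiome experiment
(control / stress / stress+drug, 6 animals per group, one fecal 16S
profile each) so that every downstream stage — diversity, differential
abundance, co-occurrence networks, behavior association — can be tested
against planted structure.

Generative model
----------------
Per taxon i and sample s, a latent log-abundance

    x_is = m_i + ln(2) * lfc_{i, g(s)} + u_is

with baseline m_i ~ Normal(0, baseline_sigma), group log2 fold effects
lfc from the config, and

    u_is = amplitude * (sqrt(rho) F_s + sqrt(1 - rho) eps_is)   (module taxa)
    u_is = latent_sigma * eps_is                                 (other taxa)

where F_s is a per-sample standard-normal factor shared within a
correlation module, giving within-module latent correlation exactly rho.
Compositions are softmax(x_.s); counts are Dirichlet-multinomial draws at
the sample's library size (Poisson around ``library_size_mean``) with a
single overdispersion scalar ``noise`` = phi, via Dirichlet concentration
p_i (1 - phi) / phi.

Behavioral indices are standardized linear functions of the linked taxa's
latent abundances plus Gaussian noise (link ``strength`` is the target
correlation on the latent scale), affinely rescaled into realistic ranges
(sucrose preference into [0, 100] percent, times clipped at 0 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .tables import BehaviorTable, CountTable, PresenceMatrix, SampleMetadata

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_study",
    "generate_presence_matrix",
    "load_config",
    "study_preset",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("Control+PBS", "CUMS+PBS", "CUMS+fluoxetine")
LN2 = np.log(2.0)

# Affine scales mapping a standardized behavioral score into realistic
# mouse ranges: (mean, sd, lower clip, upper clip).
BEHAVIOR_SCALES = {
    "SP": (75.0, 8.0, 0.0, 100.0),    # sucrose preference, percent
    "IT": (110.0, 35.0, 0.0, None),   # immobility time, s
    "OAT": (55.0, 20.0, 0.0, None),   # open-arm time, s
    "CT": (35.0, 12.0, 0.0, None),    # center time, s
}


@dataclass
class SimulationConfig:
    n_taxa: int = 40
    samples_per_group: int = 6
    groups: tuple[str, ...] = DEFAULT_GROUPS
    library_size_mean: int = 20000
    # taxon -> {group -> log2 fold effect relative to baseline}
    effect_taxa: dict[str, dict[str, float]] = field(default_factory=dict)
    # [{"taxa": [...], "rho": float, "amplitude": float (optional)}]
    correlation_modules: list[dict] = field(default_factory=list)
    # [{"taxon": str, "index": "SP"|"IT"|"OAT"|"CT", "strength": signed float}]
    behavior_links: list[dict] = field(default_factory=list)
    noise: float = 0.0003          # Dirichlet-multinomial overdispersion phi
    seed: int = 0
    baseline_sigma: float = 1.2    # spread of taxon baselines (log scale)
    latent_sigma: float = 0.35     # per-sample latent noise, non-module taxa
    module_amplitude: float = 1.5  # default co-fluctuation amplitude in modules
    baseline_offsets: dict[str, float] = field(default_factory=dict)
    # absolute log-baselines for planted taxa (overrides the random draw, so
    # planted abundance is an experimental condition, not a roll of the seed)
    pinned_baselines: dict[str, float] = field(default_factory=dict)

    def taxon_names(self) -> list[str]:
        width = max(2, len(str(self.n_taxa - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_taxa)]

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        if not 0 <= self.noise < 1:
            raise ValueError("noise (overdispersion phi) must lie in [0, 1)")
        names = set(self.taxon_names())
        for taxon, effects in self.effect_taxa.items():
            if taxon not in names:
                raise ValueError(f"effect taxon {taxon!r} not in the taxon set")
            for g in effects:
                if g not in self.groups:
                    raise ValueError(f"effect group {g!r} not declared")
        seen: set[str] = set()
        for mod in self.correlation_modules:
            rho = mod["rho"]
            if not -1 < rho < 1:
                raise ValueError(
                    f"module rho {rho} infeasible: latent correlation must "
                    "lie strictly inside (-1, 1) for a positive-definite model"
                )
            taxa = list(mod["taxa"])
            if len(taxa) < 2:
                raise ValueError("a correlation module needs >= 2 taxa")
            for t in taxa:
                if t not in names:
                    raise ValueError(f"module taxon {t!r} not in the taxon set")
                if t in seen:
                    raise ValueError(f"taxon {t!r} belongs to two modules")
                seen.add(t)
        for taxon in (*self.baseline_offsets, *self.pinned_baselines):
            if taxon not in names:
                raise ValueError(f"baseline taxon {taxon!r} not in the taxon set")
        for link in self.behavior_links:
            if link["taxon"] not in names:
                raise ValueError(f"linked taxon {link['taxon']!r} not in the taxon set")
            if link["index"] not in BEHAVIOR_SCALES:
                raise ValueError(f"unknown behavioral index {link['index']!r}")
            if not -1 <= link["strength"] <= 1:
                raise ValueError("link strength must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """Planted structure: per-contrast directions of the differential taxa,
    within-module edge list, and taxon-behavior couplings."""

    differential: dict[str, dict[tuple[str, str], int]]
    module_edges: list[tuple[str, str]]
    behavior_links: list[dict]
    latent: pd.DataFrame | None = None  # taxa x samples latent log-abundance

    def category_of(self, taxon: str, control: str, stress: str, drug: str) -> str:
        d = self.differential.get(taxon, {})
        da = d.get((control, stress), 0)
        db = d.get((stress, drug), 0)
        if da != 0 and db == -da:
            return "restored"
        if da != 0:
            return "stress_only"
        if db != 0:
            return "drug_only"
        return "unchanged"


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML key/value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "groups" in raw:
        raw["groups"] = tuple(raw["groups"])
    return SimulationConfig(**raw)


def generate_study(cfg: SimulationConfig
                   ) -> tuple[CountTable, SampleMetadata, BehaviorTable, GroundTruth]:
    """Generate (counts, metadata, behavior, ground truth); bit-reproducible
    from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa = cfg.taxon_names()
    n_taxa = cfg.n_taxa
    n_samples = cfg.samples_per_group * len(cfg.groups)
    sample_ids = [
        f"{g.replace('+', '_').replace(' ', '_')}_s{k + 1}"
        for g in cfg.groups for k in range(cfg.samples_per_group)
    ]
    sample_group = np.repeat(np.arange(len(cfg.groups)), cfg.samples_per_group)

    baseline = rng.normal(0.0, cfg.baseline_sigma, size=n_taxa)
    for taxon, off in cfg.baseline_offsets.items():
        baseline[taxa.index(taxon)] += off
    for taxon, val in cfg.pinned_baselines.items():
        baseline[taxa.index(taxon)] = val

    x = np.tile(baseline[:, None], (1, n_samples))
    for taxon, effects in cfg.effect_taxa.items():
        i = taxa.index(taxon)
        for g, lfc in effects.items():
            x[i, sample_group == cfg.groups.index(g)] += LN2 * lfc

    in_module = np.zeros(n_taxa, dtype=bool)
    for mod in cfg.correlation_modules:
        rho = mod["rho"]
        amp = mod.get("amplitude", cfg.module_amplitude)
        members = list(mod["taxa"])
        k = len(members)
        cov = np.full((k, k), float(rho))
        np.fill_diagonal(cov, 1.0)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"infeasible correlation module (rho={rho}, {k} taxa): latent "
                "equicorrelation matrix is not positive definite"
            ) from None
        u = chol @ rng.normal(size=(k, n_samples))
        for row, taxon in zip(u, members):
            i = taxa.index(taxon)
            in_module[i] = True
            x[i] += amp * row
    free = ~in_module
    x[free] += cfg.latent_sigma * rng.normal(size=(int(free.sum()), n_samples))

    comp = np.exp(x - x.max(axis=0))
    comp /= comp.sum(axis=0)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        lib = max(1, int(rng.poisson(cfg.library_size_mean)))
        if cfg.noise > 0:
            conc = comp[:, s] * (1 - cfg.noise) / cfg.noise
            q = rng.dirichlet(np.maximum(conc, 1e-9))
        else:
            q = comp[:, s]
        counts[:, s] = rng.multinomial(lib, q)

    metadata = SampleMetadata(
        {s: cfg.groups[g] for s, g in zip(sample_ids, sample_group)},
        group_order=cfg.groups,
    )

    # behavioral indices: standardized latent signal + noise, then rescaled
    behav = {}
    for index, (mu, sd, lo, hi) in BEHAVIOR_SCALES.items():
        links = [l for l in cfg.behavior_links if l["index"] == index]
        signal = np.zeros(n_samples)
        total_sq = 0.0
        for l in links:
            zi = x[taxa.index(l["taxon"])]
            zsd = zi.std()
            if zsd > 0:
                signal += l["strength"] * (zi - zi.mean()) / zsd
                total_sq += l["strength"] ** 2
        noise_sd = np.sqrt(max(0.0, 1.0 - min(total_sq, 1.0)))
        z = signal + noise_sd * rng.normal(size=n_samples)
        vals = mu + sd * z
        vals = np.clip(vals, lo, hi if hi is not None else np.inf)
        behav[index] = vals
    behavior = BehaviorTable(pd.DataFrame(behav, index=sample_ids))

    differential: dict[str, dict[tuple[str, str], int]] = {}
    for taxon, effects in cfg.effect_taxa.items():
        per_pair = {}
        for a in range(len(cfg.groups)):
            for b in range(a + 1, len(cfg.groups)):
                ga, gb = cfg.groups[a], cfg.groups[b]
                delta = effects.get(gb, 0.0) - effects.get(ga, 0.0)
                per_pair[(ga, gb)] = int(np.sign(delta))
        differential[taxon] = per_pair
    module_edges = [
        (a, b)
        for mod in cfg.correlation_modules
        for k, a in enumerate(mod["taxa"])
        for b in list(mod["taxa"])[k + 1:]
    ]
    truth = GroundTruth(differential, module_edges, list(cfg.behavior_links),
                        latent=pd.DataFrame(x, index=taxa, columns=sample_ids))

    taxonomy = {t: f"Bacteria;phylum_{i % 5};genus_{t}" for i, t in enumerate(taxa)}
    table = CountTable(taxa, sample_ids, counts, taxonomy=taxonomy)
    return table, metadata, behavior, truth


def generate_presence_matrix(n_taxa: int, n_samples: int,
                             segregation: str = "random", fill: float = 0.5,
                             seed: int | None = None) -> PresenceMatrix:
    """Seeded binary occupancy fixtures for the checkerboard machinery.

    random       iid Bernoulli(fill) cells
    checkerboard taxa paired into mutually exclusive couples (each sample
                 hosts exactly one member of each pair)
    nested       occupancy decreases down the rows over a shared sample
                 order (contains no checkerboard unit by construction)
    """
    if n_taxa < 2 or n_samples < 2:
        raise ValueError("need at least 2 taxa and 2 samples")
    if not 0 < fill < 1:
        raise ValueError("fill must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i:03d}" for i in range(n_taxa)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    if segregation == "random":
        m = (rng.random((n_taxa, n_samples)) < fill).astype(np.int64)
    elif segregation == "checkerboard":
        m = np.zeros((n_taxa, n_samples), dtype=np.int64)
        for i in range(0, n_taxa - 1, 2):
            order = rng.permutation(n_samples)
            first = order[: n_samples // 2]
            m[i, first] = 1
            m[i + 1] = 1 - m[i]
        if n_taxa % 2 == 1:  # odd taxon left over: iid occupancy
            m[-1] = (rng.random(n_samples) < fill).astype(np.int64)
    elif segregation == "nested":
        m = np.zeros((n_taxa, n_samples), dtype=np.int64)
        for rank, i in enumerate(range(n_taxa)):
            k = int(np.clip(round(2 * fill * n_samples * (n_taxa - rank)
                                  / (n_taxa + 1)), 1, n_samples))
            m[i, :k] = 1
    else:
        raise ValueError(f"unknown segregation mode: {segregation!r}")
    return PresenceMatrix(taxa, samples, m)


def study_preset(seed: int = 0) -> SimulationConfig:
    """The default synthetic study: 3 groups x 6 samples, 40 taxa, with
    planted restored / stress-only / drug-only taxa (|log2 effect| = 2), a
    5-taxon correlation module (rho = 0.9) and behavior couplings.

    Each planted category holds one up- and one down-shifted taxon whose
    baselines differ by ln(4), so the planted mass gained and lost cancel
    and the group contrast does not leak into unplanted taxa through
    compositional closure.
    """
    control, stress, drug = DEFAULT_GROUPS
    lo, hi = -1.0, -1.0 + 2 * LN2  # mass-balancing baselines for +/-2 log2 pairs
    effects = {
        # restored: shifted by stress, reversed by the drug
        "g01": {stress: 2.0},
        "g02": {stress: -2.0},
        # stress-only: shifted by stress, not corrected
        "g04": {stress: 2.0, drug: 2.0},
        "g05": {stress: -2.0, drug: -2.0},
        # drug-only: unchanged by stress, shifted by the drug
        "g07": {drug: 2.0},
        "g08": {drug: -2.0},
    }
    pins = {"g01": lo, "g02": hi, "g04": lo, "g05": hi, "g07": lo, "g08": hi}
    pins.update({f"g{i}": -1.0 for i in range(10, 15)})
    return SimulationConfig(
        effect_taxa=effects,
        correlation_modules=[{"taxa": ["g10", "g11", "g12", "g13", "g14"],
                              "rho": 0.9}],
        behavior_links=[
            {"taxon": "g01", "index": "SP", "strength": -0.8},
            {"taxon": "g01", "index": "IT", "strength": 0.7},
            {"taxon": "g02", "index": "OAT", "strength": 0.6},
        ],
        pinned_baselines=pins,
        seed=seed,
    )


def module_preset(seed: int = 0, samples: int = 20) -> SimulationConfig:
    """Single-cohort scenario for co-occurrence recovery: 30 taxa, one
    5-taxon module at rho = 0.9 over ``samples`` samples."""
    module = [f"g{i}" for i in range(10, 15)]
    return SimulationConfig(
        n_taxa=30,
        samples_per_group=samples,
        groups=("all",),
        correlation_modules=[{"taxa": module, "rho": 0.9}],
        pinned_baselines={t: -1.0 for t in module},
        seed=seed,
    )
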