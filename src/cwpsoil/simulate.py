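"""Synthetic survey generator with planted ground truth.

Emulates the statistical structure of a global soil survey of crop wild
progenitor (CWP) habitats: 125 wild populations of 10 CWP species whose
edaphoclimatic conditions cluster into 4 latent ecoregions driven by 2
environmental gradients; per-kingdom phylotype count tables in which a
small planted core dominates the reads; co-occurrence modules of core taxa
tied to single ecoregions through elevated presence probability and
abundance; and module responses linearly coupled to environmental
predictors with a CWP-level random intercept.  Every quantity the pipeline
is meant to recover (ecoregion labels, core membership, module partition,
effect sizes) is recorded in :class:`SyntheticTruth`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

CWP_SPECIES = (
    "maize", "rice", "wheat", "potato", "bean",
    "little_millet", "barley", "sunflower", "soya", "cotton",
)

#: 18 edaphoclimatic variables on (offset, scale) affine maps of the latent
#: gradients; names match the driver-model predictor vocabulary.
DEFAULT_ENV_VARIABLES: dict[str, tuple[float, float]] = {
    "MAT": (15.0, 4.0), "MAP": (800.0, 150.0), "PSEA": (40.0, 8.0),
    "MDR": (11.0, 2.0), "AI": (1.0, 0.15), "NDVI": (0.5, 0.08),
    "SOC": (25.0, 4.0), "pH": (6.5, 0.5), "conductivity": (1.0, 0.15),
    "sand": (50.0, 8.0), "NH4": (50.0, 8.0), "NO3": (50.0, 8.0),
    "PO4": (50.0, 8.0), "Ca": (50.0, 8.0), "K": (50.0, 8.0),
    "Mg": (50.0, 8.0), "Fe": (50.0, 8.0), "Zn": (50.0, 8.0),
}


@dataclasses.dataclass
class SyntheticTruth:
    """Planted structure recorded by the generator."""

    k_ecoregions: int = 0
    site_ecoregion: pd.Series | None = None            # site -> 0..k-1
    gradient_loadings: pd.DataFrame | None = None      # variable x 2 factors
    missing_mask: set = dataclasses.field(default_factory=set)
    core_taxa: dict = dataclasses.field(default_factory=dict)          # kingdom -> set
    module_membership: dict = dataclasses.field(default_factory=dict)  # kingdom -> {taxon: module}
    module_ecoregion: dict = dataclasses.field(default_factory=dict)   # kingdom -> {module: ecoregion}
    effect_sizes: dict = dataclasses.field(default_factory=dict)       # predictor -> slope
    random_intercepts: dict = dataclasses.field(default_factory=dict)  # cwp -> intercept


@dataclasses.dataclass
class KingdomConfig:
    """Per-kingdom count-table generator settings."""

    n_taxa: int = 2000
    core_fraction: float = 0.02
    n_modules: int = 2
    depth_mean: float = 30000.0
    depth_sigma: float = 0.2
    overdispersion: float = 200.0      # Dirichlet concentration
    module_multiplier: float = 8.0     # abundance boost in the linked ecoregion
    presence_in: float = 0.97          # presence prob in the linked ecoregion
    presence_out: float = 0.25         # presence prob elsewhere
    core_read_share: float = 0.2       # base (un-boosted) read mass of core taxa;
                                       # ecoregion boosts raise the realized share
    noncore_max_cwps: int = 3          # non-core taxa occur in 1..this many CWPs
    noncore_presence: float = 0.5


#: Per-kingdom configs mirroring the survey's scale (richness placeholders
#: are configurable; depths sit comfortably above the rarefaction depths).
PAPER_KINGDOM_CONFIGS: dict[str, KingdomConfig] = {
    "bacteria": KingdomConfig(n_taxa=2000, core_fraction=0.02, depth_mean=30000.0),
    "fungi": KingdomConfig(n_taxa=1500, core_fraction=0.02, depth_mean=20000.0),
    "protists": KingdomConfig(n_taxa=800, core_fraction=0.03, depth_mean=12500.0),
    "invertebrates": KingdomConfig(n_taxa=300, core_fraction=0.05, depth_mean=650.0),
}

#: Reduced taxon counts for desk-scale runs; planted structure unchanged.
DESK_KINGDOM_CONFIGS: dict[str, KingdomConfig] = {
    "bacteria": KingdomConfig(n_taxa=500, core_fraction=0.08, depth_mean=30000.0),
    "fungi": KingdomConfig(n_taxa=400, core_fraction=0.08, depth_mean=20000.0),
    "protists": KingdomConfig(n_taxa=300, core_fraction=0.08, depth_mean=12500.0),
    "invertebrates": KingdomConfig(n_taxa=150, core_fraction=0.10, depth_mean=650.0),
}


def simulate_sites(
    n_sites: int = 125,
    n_cwps: int = 10,
    k_ecoregions: int = 4,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Site metadata with CWP species and latent ecoregion labels.

    Sites are partitioned across CWP species (10-15 per species at the
    default n=125); each CWP is concentrated in one primary ecoregion with a
    30% spillover into a secondary one, so ecoregions host overlapping sets
    of species.  Coordinates are drawn around per-ecoregion centres.
    """
    if not n_sites >= n_cwps >= 1:
        raise ValueError("need n_sites >= n_cwps >= 1")
    if not 1 <= k_ecoregions <= n_sites:
        raise ValueError("k_ecoregions must be in [1, n_sites]")
    rng = np.random.default_rng(seed)
    base, cap = divmod_sizes(n_sites, n_cwps, rng)
    species = np.repeat(np.array(CWP_SPECIES[:n_cwps] if n_cwps <= 10 else
                                 [f"cwp_{i}" for i in range(n_cwps)]), base)
    ecoregion = np.empty(n_sites, dtype=int)
    pos = 0
    for i, n_i in enumerate(base):
        primary = i % k_ecoregions
        secondary = (i + 1) % k_ecoregions
        pick = rng.random(n_i) < 0.7
        ecoregion[pos:pos + n_i] = np.where(pick, primary, secondary)
        pos += n_i
    centers_lat = np.linspace(-35, 45, k_ecoregions)
    centers_lon = np.linspace(-100, 110, k_ecoregions)
    lat = np.clip(centers_lat[ecoregion] + rng.normal(0, 3, n_sites), -90, 90)
    lon = np.clip(centers_lon[ecoregion] + rng.normal(0, 3, n_sites), -180, 180)
    site_ids = [f"site_{i:03d}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {
            "cwp_species": species,
            "latitude": np.round(lat, 4),
            "longitude": np.round(lon, 4),
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    truth = SyntheticTruth(
        k_ecoregions=k_ecoregions,
        site_ecoregion=pd.Series(ecoregion, index=sites.index, name="ecoregion"),
    )
    return sites, truth


def divmod_sizes(n_sites: int, n_cwps: int, rng) -> tuple[np.ndarray, int]:
    """Random per-CWP site counts in [floor, floor+5] summing to n_sites."""
    floor = max(1, n_sites // n_cwps - 2)
    cap = min(n_sites, floor + 5)
    sizes = np.full(n_cwps, floor)
    remaining = n_sites - sizes.sum()
    if remaining < 0:
        sizes = np.full(n_cwps, n_sites // n_cwps)
        sizes[: n_sites % n_cwps] += 1
        return sizes, int(sizes.max())
    while remaining > 0:
        open_slots = np.flatnonzero(sizes < cap)
        if len(open_slots) == 0:
            cap += 1
            continue
        sizes[rng.choice(open_slots)] += 1
        remaining -= 1
    return sizes, cap


def _ecoregion_centroids(k: int) -> np.ndarray:
    """Well-separated centroids on a circle in the 2-D gradient space."""
    angles = 2 * np.pi * np.arange(k) / k + np.pi / k
    return 2.5 * np.column_stack([np.cos(angles), np.sin(angles)])


def simulate_environment(
    sites: pd.DataFrame,
    truth: SyntheticTruth,
    n_vars: int = 18,
    noise_sd: float = 0.5,
    missing_fraction: float = 0.04,
    seed: int | None = None,
    variables: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Edaphoclimatic table driven by 2 latent gradients.

    Each variable is an affine map of a linear combination of the two
    latent factors (whose levels are the ecoregion centroids) plus Gaussian
    noise of ``noise_sd`` on the latent scale; cells are then blanked
    completely at random at ``missing_fraction`` and recorded in the truth.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if variables is None:
        names = list(DEFAULT_ENV_VARIABLES)[:n_vars]
        if n_vars > len(DEFAULT_ENV_VARIABLES):
            names += [f"env_{i}" for i in range(len(DEFAULT_ENV_VARIABLES), n_vars)]
        scales = {
            n: DEFAULT_ENV_VARIABLES.get(n, (0.0, 1.0)) for n in names
        }
    else:
        names = list(variables)[:n_vars]
        scales = dict(variables)
    loadings = rng.uniform(-1.0, 1.0, size=(len(names), 2))
    # guarantee every variable carries gradient signal
    weak = np.abs(loadings).sum(axis=1) < 0.3
    loadings[weak] = np.sign(loadings[weak]) * 0.5 + (loadings[weak] == 0) * 0.5
    centroids = _ecoregion_centroids(truth.k_ecoregions)
    factors = centroids[truth.site_ecoregion.loc[sites.index].to_numpy()]
    latent = factors @ loadings.T + rng.normal(0, noise_sd, (len(sites), len(names)))
    data = {}
    for j, name in enumerate(names):
        mu, scale = scales[name]
        data[name] = mu + scale * latent[:, j]
    env = pd.DataFrame(data, index=sites.index)
    if missing_fraction > 0:
        mask = rng.random(env.shape) < missing_fraction
        env = env.mask(mask)
        truth.missing_mask = {
            (env.index[i], env.columns[j]) for i, j in zip(*np.nonzero(mask))
        }
    truth.gradient_loadings = pd.DataFrame(
        loadings, index=names, columns=["factor_1", "factor_2"]
    )
    return env


def simulate_counts(
    sites: pd.DataFrame,
    truth: SyntheticTruth,
    kingdom: str,
    cfg: KingdomConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Phylotype count table with a planted core and ecoregion-tied modules.

    The planted core (top ``core_fraction`` of taxa) receives most of the
    Dirichlet concentration, so it dominates reads while being a small
    minority of taxa.  Core taxa are split into ``n_modules`` modules, each
    linked to one ecoregion: inside it they are near-ubiquitous
    (``presence_in``) and boosted ``module_multiplier``-fold in expected
    abundance; elsewhere they occur at ``presence_out``.  Non-core taxa are
    confined to the sites of 1..``noncore_max_cwps`` CWP species, so they
    can never satisfy the prevalence criterion.  Counts are multinomial
    draws at lognormal depths from Dirichlet-perturbed proportions
    (compositional overdispersion).
    """
    cfg = cfg or KingdomConfig()
    if cfg.n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    if cfg.n_modules < 1:
        raise ValueError("need at least 1 module")
    if not 0 < cfg.core_fraction < 1:
        raise ValueError("core_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    eco = truth.site_ecoregion.loc[sites.index].to_numpy()
    k = truth.k_ecoregions

    n_core = max(cfg.n_modules, round(cfg.core_fraction * cfg.n_taxa))
    taxa = [f"{kingdom[:3]}_zotu{i:04d}" for i in range(cfg.n_taxa)]
    core = taxa[:n_core]
    module_of = {t: (i % cfg.n_modules) + 1 for i, t in enumerate(core)}
    module_eco = {m: (m - 1) % k for m in range(1, cfg.n_modules + 1)}

    # base relative weights: core mass = core_read_share
    w = np.empty(cfg.n_taxa)
    core_w = rng.lognormal(0.0, 0.5, n_core)
    w[:n_core] = core_w / core_w.sum() * cfg.core_read_share
    tail_w = rng.lognormal(0.0, 1.0, cfg.n_taxa - n_core)
    w[n_core:] = tail_w / tail_w.sum() * (1 - cfg.core_read_share)

    # presence gates and ecoregion multipliers
    gate = np.zeros((cfg.n_taxa, n_sites))
    mult = np.ones((cfg.n_taxa, n_sites))
    for i, t in enumerate(core):
        home = module_eco[module_of[t]]
        in_home = eco == home
        p = np.where(in_home, cfg.presence_in, cfg.presence_out)
        gate[i] = rng.random(n_sites) < p
        mult[i] = np.where(in_home, cfg.module_multiplier, 1.0)
    cwps = sites["cwp_species"].to_numpy()
    cwp_names = pd.unique(cwps)
    for i in range(n_core, cfg.n_taxa):
        n_own = rng.integers(1, cfg.noncore_max_cwps + 1)
        own = rng.choice(cwp_names, size=n_own, replace=False)
        eligible = np.isin(cwps, own)
        gate[i] = eligible & (rng.random(n_sites) < cfg.noncore_presence)
    # keep entirely-absent non-core taxa (legal: zero rows), but core taxa
    # must satisfy the planted-prevalence invariant
    _check_core_prevalence(gate[:n_core], cwps, min_cwps=4)

    expected = w[:, None] * gate * mult
    depths = rng.lognormal(np.log(cfg.depth_mean), cfg.depth_sigma, n_sites)
    counts = np.zeros((cfg.n_taxa, n_sites), dtype=np.int64)
    for s in range(n_sites):
        alpha = cfg.overdispersion * expected[:, s]
        nz = alpha > 0
        if not nz.any():
            continue
        props = np.zeros(cfg.n_taxa)
        gamma = rng.gamma(alpha[nz])
        total = gamma.sum()
        if total <= 0:
            props[nz] = expected[nz, s] / expected[nz, s].sum()
        else:
            props[nz] = gamma / total
        counts[:, s] = rng.multinomial(int(depths[s]), props)

    truth.core_taxa[kingdom] = set(core)
    truth.module_membership[kingdom] = module_of
    truth.module_ecoregion[kingdom] = module_eco
    return pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=sites.index)


def _check_core_prevalence(core_gate: np.ndarray, cwps: np.ndarray, min_cwps: int) -> None:
    df = pd.DataFrame(core_gate > 0, columns=cwps)
    prevalence = df.T.groupby(level=0).any().sum(axis=0)
    if (prevalence < min_cwps).any():
        bad = int((prevalence < min_cwps).sum())
        raise RuntimeError(
            f"planted core violated the prevalence invariant for {bad} taxa; "
            "increase presence_out or site counts"
        )


def simulate_module_response(
    truth: SyntheticTruth,
    env: pd.DataFrame,
    sites: pd.DataFrame,
    effect_sizes: dict[str, float],
    sigma_cwp: float = 0.5,
    sigma_resid: float = 0.5,
    seed: int | None = None,
) -> pd.Series:
    """Per-site module response with known slopes and CWP random intercepts.

    response_i = sum_g beta_g x_ig + u_cwp(i) + eps_i with u ~ N(0,
    sigma_cwp^2) and eps ~ N(0, sigma_resid^2).  Used for mixed-model
    parameter-recovery experiments independent of the count simulator.
    """
    unknown = [p for p in effect_sizes if p not in env.columns]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")
    if sigma_cwp < 0 or sigma_resid < 0:
        raise ValueError("variance components must be nonnegative")
    rng = np.random.default_rng(seed)
    cwps = sites.loc[env.index, "cwp_species"]
    intercepts = {
        c: rng.normal(0.0, sigma_cwp) for c in pd.unique(cwps)
    }
    y = np.zeros(len(env))
    for pred, beta in effect_sizes.items():
        y = y + beta * env[pred].to_numpy(dtype=float)
    y = y + cwps.map(intercepts).to_numpy() + rng.normal(0, sigma_resid, len(env))
    truth.effect_sizes = dict(effect_sizes)
    truth.random_intercepts = intercepts
    return pd.Series(y, index=env.index, name="module_response")


def simulate_dataset(
    preset: str = "desk",
    seed: int | None = None,
    n_sites: int = 125,
    n_cwps: int = 10,
    k_ecoregions: int = 4,
    noise_sd: float = 0.5,
    missing_fraction: float = 0.04,
) -> dict:
    """Full synthetic survey: sites, environment, four count tables, truth.

    ``preset='paper'`` uses the survey-scale taxon counts
    (2000/1500/800/300); ``preset='desk'`` keeps the identical planted
    structure at reduced richness for fast test runs.
    """
    configs = {"paper": PAPER_KINGDOM_CONFIGS, "desk": DESK_KINGDOM_CONFIGS}[preset]
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=6)
    sites, truth = simulate_sites(n_sites, n_cwps, k_ecoregions, seed=int(seeds[0]))
    env = simulate_environment(
        sites, truth, noise_sd=noise_sd, missing_fraction=missing_fraction,
        seed=int(seeds[1]),
    )
    counts = {
        kingdom: simulate_counts(sites, truth, kingdom, cfg, seed=int(seeds[2 + i]))
        for i, (kingdom, cfg) in enumerate(configs.items())
    }
    return {"sites": sites, "env": env, "counts": counts, "truth": truth}


def matched_accuracy(truth_labels: pd.Series, predicted: pd.Series) -> float:
    """Clustering accuracy after optimal (Hungarian) label matching."""
    truth_labels, predicted = truth_labels.align(predicted, join="inner")
    t_codes, _ = pd.factorize(truth_labels)
    p_codes, _ = pd.factorize(predicted)
    k = max(t_codes.max(), p_codes.max()) + 1
    conf = np.zeros((k, k))
    np.add.at(conf, (t_codes, p_codes), 1)
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(truth_labels)
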