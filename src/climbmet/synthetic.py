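"""Synthetic-data generators for every input of the pipeline.

The generators emulate the structure of a climbing-fractionation study on an
isogenic fly cohort: Gompertz lifespans conditional on survival to the
fractionation age, three-round climbing trials, a samples-by-metabolites
abundance matrix with planted fraction effects and fraction-dependent pair
covariance, a layered KEGG-style heterogeneous metabolic graph, and per-vial
mechanical-stress (bang) assay counts.

All randomness flows from a single integer seed per call; there is no global
state.  Default parameter values encode the study conditions the package is
built around (five ordinal fractions, two sampling ages, three extraction
batches, ~71 metabolome samples, mean lifespans spanning ~45.6 to ~50.3
days); see docs/methods.md for how they were chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fractionation import FRACTION_NAMES, branching_probabilities

__all__ = [
    "CohortSpec",
    "MetabolomeSpec",
    "GraphSpec",
    "simulate_lifespans",
    "simulate_fractionation",
    "simulate_metabolome",
    "simulate_hetero_graph",
    "simulate_bang_assay",
    "default_metabolome_spec",
]

# Per-fraction Gompertz defaults (bottom .. top).  beta falls and the implied
# unconditional mean lifespan rises with climbing fraction; alpha was solved
# numerically so the means are 45.6, 47.2, 48.3, 49.4, 50.3 days.
_DEFAULT_ALPHA = (1.3365e-4, 2.36789e-4, 3.09753e-4, 2.73972e-4, 3.75521e-4)
_DEFAULT_BETA = (0.14, 0.12, 0.11, 0.11, 0.10)
#: Fraction probabilities implied by the three-round branching at p=0.5.
_DEFAULT_FRACTION_PROBS = tuple(branching_probabilities(0.5))

CENSUS_INTERVAL_DAYS = 2.5


@dataclass
class CohortSpec:
    """Design of a simulated demography cohort."""

    n_flies: int = 2000
    fraction_probs: Sequence[float] = _DEFAULT_FRACTION_PROBS
    alpha_by_fraction: Sequence[float] = _DEFAULT_ALPHA
    beta_by_fraction: Sequence[float] = _DEFAULT_BETA
    entry_age_days: float = 29.0
    censor_prob: float = 0.01
    flies_per_vial: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.fraction_probs, dtype=float)
        if p.shape != (5,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("fraction_probs must be 5 probabilities summing to 1")
        a = np.asarray(self.alpha_by_fraction, dtype=float)
        b = np.asarray(self.beta_by_fraction, dtype=float)
        if a.shape != (5,) or np.any(a <= 0):
            raise ValueError("alpha_by_fraction must be 5 positive rates")
        if b.shape != (5,) or np.any(b < 0):
            raise ValueError("beta_by_fraction must be 5 nonnegative slopes")
        if self.entry_age_days < 0:
            raise ValueError("entry_age_days must be nonnegative")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ValueError("censor_prob must be in [0, 1)")
        if self.n_flies < 1:
            raise ValueError("n_flies must be positive")


def _gompertz_inverse_cdf(u: np.ndarray, alpha: np.ndarray, beta: np.ndarray,
                          entry: float) -> np.ndarray:
    """Death ages T with S(T | entry) = u under hazard alpha*exp(beta*t).

    T = entry + (1/beta) * ln(1 - beta*ln(u) / (alpha*e^{beta*entry})); the
    beta -> 0 limit is the left-truncated exponential entry - ln(u)/alpha.
    """
    u = np.asarray(u, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), u.shape)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), u.shape)
    out = np.empty_like(u)
    zero = beta < 1e-12
    if np.any(zero):
        out[zero] = entry - np.log(u[zero]) / alpha[zero]
    nz = ~zero
    if np.any(nz):
        b, a = beta[nz], alpha[nz]
        out[nz] = entry + np.log1p(-b * np.log(u[nz]) / (a * np.exp(b * entry))) / b
    return out


def simulate_lifespans(spec: CohortSpec) -> pd.DataFrame:
    """Simulate per-fly survival records conditional on survival to entry age.

    Each fly draws an ordinal climbing fraction from ``fraction_probs`` and a
    death age from the Gompertz distribution of its fraction, conditional on
    being alive at ``entry_age_days`` (exact inverse-CDF sampling).
    Censoring emulates escapes during vial transfers: at each census (every
    2.5 days) a live fly is censored with probability ``censor_prob``.

    Returns a DataFrame with columns
    ``fly_id, vial, fraction, entry_age, exit_age, event`` (event 1=death,
    0=censored).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_flies
    frac = rng.choice(5, size=n, p=np.asarray(spec.fraction_probs, dtype=float))
    alpha = np.asarray(spec.alpha_by_fraction, dtype=float)[frac]
    beta = np.asarray(spec.beta_by_fraction, dtype=float)[frac]
    u = rng.uniform(size=n)
    death = _gompertz_inverse_cdf(u, alpha, beta, spec.entry_age_days)

    exit_age = death
    event = np.ones(n, dtype=int)
    if spec.censor_prob > 0:
        # geometric number of censuses survived before the censoring event
        g = rng.geometric(spec.censor_prob, size=n)
        censor_age = spec.entry_age_days + CENSUS_INTERVAL_DAYS * g
        censored = censor_age < death
        exit_age = np.where(censored, censor_age, death)
        event = np.where(censored, 0, 1)

    # vial assignment within fraction, ~flies_per_vial flies per vial
    vial = np.empty(n, dtype=object)
    for f in range(5):
        idx = np.flatnonzero(frac == f)
        for j, i in enumerate(idx):
            vial[i] = f"{FRACTION_NAMES[f]}-v{j // spec.flies_per_vial + 1}"

    return pd.DataFrame(
        {
            "fly_id": [f"fly{i:05d}" for i in range(n)],
            "vial": vial,
            "fraction": frac,
            "entry_age": spec.entry_age_days,
            "exit_age": exit_age,
            "event": event,
        }
    )


PropensityLike = float | Sequence[float] | Callable[[np.random.Generator, int], np.ndarray]


def simulate_fractionation(
    n_flies: int,
    p_top: PropensityLike = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate three-round climbing trials and the resulting fraction labels.

    ``p_top`` is each fly's per-round probability of ending above the
    partition; it may be a scalar, a length-``n_flies`` array, or a callable
    ``f(rng, n) -> array`` drawing per-fly propensities (the within-cohort
    propensity distribution is deliberately pluggable).

    Returns a DataFrame with columns ``fly_id, round1, round2, round3,
    fraction`` where ``round3`` is empty for flies that stopped after two
    discordant rounds (labelled "middle").
    """
    if n_flies < 1:
        raise ValueError("n_flies must be positive")
    rng = np.random.default_rng(seed)
    if callable(p_top):
        p = np.asarray(p_top(rng, n_flies), dtype=float)
    else:
        p = np.broadcast_to(np.asarray(p_top, dtype=float), (n_flies,)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("climbing propensities must lie in [0, 1]")

    r1 = rng.uniform(size=n_flies) < p
    r2 = rng.uniform(size=n_flies) < p
    concordant = r1 == r2
    r3 = np.where(concordant, rng.uniform(size=n_flies) < p, False)

    # branching labels: TTT=4, TTB=3, discordant=2, BBT=1, BBB=0
    fraction = np.full(n_flies, 2, dtype=int)
    fraction[r1 & r2 & r3] = 4
    fraction[r1 & r2 & ~r3] = 3
    fraction[~r1 & ~r2 & r3] = 1
    fraction[~r1 & ~r2 & ~r3] = 0

    def sym(b: np.ndarray) -> np.ndarray:
        return np.where(b, "T", "B")

    round3 = np.where(concordant, sym(r3), "")
    return pd.DataFrame(
        {
            "fly_id": [f"fly{i:05d}" for i in range(n_flies)],
            "round1": sym(r1),
            "round2": sym(r2),
            "round3": round3,
            "fraction": fraction,
        }
    )


@dataclass
class MetabolomeSpec:
    """Design of a simulated metabolome experiment.

    ``group_mean_shifts`` is an (n_metabolites, 5) matrix of additive
    fraction effects on the log scale; ``planted_pairs`` is a list of
    ``(i, k, rho_by_fraction)`` tuples inducing fraction-dependent pairwise
    correlation through a shared latent factor with fraction-specific
    loadings.  Batch location/scale distortions and a linear run-order drift
    are applied last, emulating the artifacts the preprocessing stage is
    meant to remove.
    """

    n_samples: int = 71
    n_metabolites: int = 160
    n_batches: int = 3
    group_mean_shifts: np.ndarray | None = None
    age_shifts: np.ndarray | None = None
    planted_pairs: Sequence[tuple[int, int, Sequence[float]]] = field(default_factory=list)
    batch_shifts: Sequence[float] | None = None
    batch_scales: Sequence[float] | None = None
    run_order_slope: float = 0.0
    noise_sd: float = 1.0
    n_week4_replicates: int = 4
    n_week6_replicates: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10 or self.n_metabolites < 2 or self.n_batches < 1:
            raise ValueError("need >=10 samples, >=2 metabolites, >=1 batch")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.group_mean_shifts is not None:
            gms = np.asarray(self.group_mean_shifts, dtype=float)
            if gms.shape != (self.n_metabolites, 5):
                raise ValueError("group_mean_shifts must be (n_metabolites, 5)")
            self.group_mean_shifts = gms
        if self.age_shifts is not None:
            ash = np.asarray(self.age_shifts, dtype=float)
            if ash.shape != (self.n_metabolites,):
                raise ValueError("age_shifts must be length n_metabolites")
            self.age_shifts = ash
        if self.batch_shifts is None:
            self.batch_shifts = tuple([0.0] * self.n_batches)
        if self.batch_scales is None:
            self.batch_scales = tuple([1.0] * self.n_batches)
        if len(self.batch_shifts) != self.n_batches or len(self.batch_scales) != self.n_batches:
            raise ValueError("batch_shifts/batch_scales must have length n_batches")
        if np.any(np.asarray(self.batch_scales, dtype=float) <= 0):
            raise ValueError("batch_scales must be positive")
        seen = set()
        for i, k, rho in self.planted_pairs:
            if not (0 <= i < self.n_metabolites and 0 <= k < self.n_metabolites and i != k):
                raise ValueError(f"invalid planted pair ({i}, {k})")
            key = (min(i, k), max(i, k))
            if key in seen:
                raise ValueError(f"planted pair {key} listed twice")
            seen.add(key)
            r = np.asarray(rho, dtype=float)
            if r.shape != (5,) or np.any(np.abs(r) >= 1):
                raise ValueError("per-fraction rho must be 5 values with |rho| < 1")


def _sample_metadata(spec: MetabolomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Distribute samples over the 5 fractions x 2 ages design.

    Samples are spread as evenly as possible over the 10 cells, remainders
    going to Week-6 cells first (the study sampled Week 6 more densely);
    within an age, samples of a fraction cycle over that age's replicate
    fractionation procedures.
    """
    cells = [(age, f) for age in (6, 4) for f in range(5)]  # week-6 cells first
    base, extra = divmod(spec.n_samples, 10)
    counts = {cell: base + (1 if j < extra else 0) for j, cell in enumerate(cells)}
    rows = []
    for (age, f), c in counts.items():
        nrep = spec.n_week4_replicates if age == 4 else spec.n_week6_replicates
        for j in range(c):
            rep = f"W{age}R{j % nrep + 1}"
            rows.append({"age_week": age, "fraction": f, "replicate": rep})
    meta = pd.DataFrame(rows)
    meta = meta.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31 - 1)))
    meta = meta.reset_index(drop=True)
    meta.index = [f"s{i:03d}" for i in range(len(meta))]
    # contiguous extraction batches over the shuffled order, then a run order
    # unique within each batch
    batch = np.array_split(np.arange(len(meta)), spec.n_batches)
    meta["batch"] = 0
    for b, idx in enumerate(batch):
        meta.iloc[idx, meta.columns.get_loc("batch")] = b
    meta["run_order"] = meta.groupby("batch").cumcount() + 1
    return meta


def simulate_metabolome(spec: MetabolomeSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log-scale abundance matrix plus sample metadata.

    abundance = baseline + fraction shift + age shift + latent pair factors
    + iid noise, then per-batch location/scale distortion and linear
    run-order drift.  Returns ``(matrix, meta)`` where ``matrix`` is
    samples x metabolites and ``meta`` carries ``age_week, fraction,
    replicate, batch, run_order`` per sample.
    """
    rng = np.random.default_rng(spec.seed)
    meta = _sample_metadata(spec, rng)
    n, m = len(meta), spec.n_metabolites
    frac = meta["fraction"].to_numpy()

    baseline = rng.normal(0.0, 1.0, size=m)
    x = np.tile(baseline, (n, 1))
    if spec.group_mean_shifts is not None:
        x += spec.group_mean_shifts.T[frac, :]
    if spec.age_shifts is not None:
        x += np.outer((meta["age_week"].to_numpy() == 6).astype(float), spec.age_shifts)

    for i, k, rho in spec.planted_pairs:
        r = np.asarray(rho, dtype=float)[frac]
        lam = spec.noise_sd * np.sqrt(np.abs(r) / (1.0 - np.abs(r)))
        z = rng.normal(size=n)
        x[:, i] += lam * z
        x[:, k] += np.sign(r) * lam * z

    x += rng.normal(0.0, spec.noise_sd, size=(n, m))

    shifts = np.asarray(spec.batch_shifts, dtype=float)[meta["batch"].to_numpy()]
    scales = np.asarray(spec.batch_scales, dtype=float)[meta["batch"].to_numpy()]
    x = x * scales[:, None] + shifts[:, None]
    x += spec.run_order_slope * meta["run_order"].to_numpy()[:, None]

    cols = [f"met{j:03d}" for j in range(m)]
    return pd.DataFrame(x, index=meta.index, columns=cols), meta


def default_metabolome_spec(
    seed: int = 0,
    n_shift_metabolites: int = 9,
    shift_sd: float = 1.0,
    n_diff_pairs: int = 10,
    rho_bottom: float = 0.8,
    rho_top: float = 0.0,
) -> MetabolomeSpec:
    """The study-conditions metabolome: 160 metabolites, ~71 samples, three
    batches, nine planted monotone-shift metabolites (half up, half down with
    climbing) and ten pairs whose correlation decays from ``rho_bottom`` in
    the bottom fraction to ``rho_top`` in the top fraction.
    """
    m = 160
    gms = np.zeros((m, 5))
    levels = np.linspace(-0.5, 0.5, 5) * shift_sd * 2  # +-1 SD span across fractions
    for j in range(n_shift_metabolites):
        gms[j] = levels if j % 2 == 0 else -levels
    rho_grid = np.linspace(rho_bottom, rho_top, 5)
    pairs = [(n_shift_metabolites + 2 * t, n_shift_metabolites + 2 * t + 1, tuple(rho_grid))
             for t in range(n_diff_pairs)]
    return MetabolomeSpec(
        n_samples=71,
        n_metabolites=m,
        n_batches=3,
        group_mean_shifts=gms,
        age_shifts=np.concatenate([np.full(20, 0.8), np.zeros(m - 20)]),
        planted_pairs=pairs,
        batch_shifts=(0.0, 0.6, -0.6),
        batch_scales=(1.0, 1.15, 0.9),
        run_order_slope=0.01,
        noise_sd=1.0,
        seed=seed,
    )


@dataclass
class GraphSpec:
    """Design of a layered KEGG-style heterogeneous graph.

    Node classes are metabolite, reaction, enzyme, pathway, module; edges
    never join two metabolites (metabolites connect through reactions,
    enzymes, pathways and modules).  Wiring densities are mean attachment
    counts per node of the named class.
    """

    n_metabolites: int = 40
    n_reactions: int = 60
    n_enzymes: int = 15
    n_pathways: int = 8
    n_modules: int = 5
    reaction_metabolites: float = 2.4
    enzyme_reactions: float = 3.0
    pathway_members: float = 8.0
    module_members: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_reactions", "n_enzymes", "n_pathways", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.reaction_metabolites < 2:
            raise ValueError(
                "reaction_metabolites must be >= 2: reactions are the only "
                "guaranteed connectors of metabolites, so sparser wiring "
                "cannot satisfy the no-metabolite-edge connectivity invariant"
            )
        for name in ("enzyme_reactions", "pathway_members", "module_members"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def simulate_hetero_graph(spec: GraphSpec):
    """Generate a layered random heterogeneous graph.

    Reactions attach to random metabolite sets (>=2 each), enzymes to
    reactions, pathways to reactions/metabolites/enzymes, and modules to
    pathways/reactions/metabolites.  Metabolites left outside the largest
    connected component are re-attached through a reaction in it, so the
    largest component contains every metabolite.  Returns a
    :class:`climbmet.keggnet.HeteroGraph`.
    """
    from .keggnet import HeteroGraph  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    mets = [f"C{i:05d}" for i in range(spec.n_metabolites)]
    rxns = [f"R{i:05d}" for i in range(spec.n_reactions)]
    enzs = [f"E{i:04d}" for i in range(spec.n_enzymes)]
    pwys = [f"P{i:04d}" for i in range(spec.n_pathways)]
    mods = [f"M{i:04d}" for i in range(spec.n_modules)]
    classes = {}
    for names, k in ((mets, "metabolite"), (rxns, "reaction"), (enzs, "enzyme"),
                     (pwys, "pathway"), (mods, "module")):
        classes.update({nm: k for nm in names})

    def n_attach(mean: float, lo: int = 1) -> int:
        return max(lo, int(rng.poisson(mean)))

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    for r in rxns:
        for c in rng.choice(spec.n_metabolites, size=min(spec.n_metabolites,
                            n_attach(spec.reaction_metabolites, lo=2)), replace=False):
            add(r, mets[c])
    for e in enzs:
        for j in rng.choice(spec.n_reactions, size=min(spec.n_reactions,
                            n_attach(spec.enzyme_reactions)), replace=False):
            add(e, rxns[j])
    non_met_pool = rxns + enzs
    for p in pwys:
        members = rng.choice(len(non_met_pool) + spec.n_metabolites,
                             size=min(len(non_met_pool) + spec.n_metabolites,
                                      n_attach(spec.pathway_members, lo=2)), replace=False)
        for j in members:
            add(p, non_met_pool[j] if j < len(non_met_pool) else mets[j - len(non_met_pool)])
    mod_pool = pwys + rxns
    for mo in mods:
        members = rng.choice(len(mod_pool) + spec.n_metabolites,
                             size=min(len(mod_pool) + spec.n_metabolites,
                                      n_attach(spec.module_members, lo=2)), replace=False)
        for j in members:
            add(mo, mod_pool[j] if j < len(mod_pool) else mets[j - len(mod_pool)])

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from((nm, {"klass": k}) for nm, k in classes.items())
    g.add_edges_from(edges)

    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    main = comps[0]
    rxn_in_main = [r for r in rxns if r in main]
    for comp in comps[1:]:
        stray = [v for v in comp if classes[v] == "metabolite"]
        anchor = [v for v in comp if classes[v] != "metabolite"]
        if stray and rxn_in_main:
            # bridge through a reaction so the no-metabolite-edge rule holds
            g.add_edge(stray[0], rxn_in_main[int(rng.integers(len(rxn_in_main)))])
        elif anchor and rxn_in_main:
            g.add_edge(anchor[0], rxn_in_main[int(rng.integers(len(rxn_in_main)))])

    return HeteroGraph(g)


def simulate_bang_assay(
    p_by_fraction: Sequence[float] = (0.69, 0.75, 0.82, 0.88, 0.92),
    n_vials: int = 9,
    flies_per_vial: tuple[int, int] | int = (20, 25),
    seed: int = 0,
    n_control_vials: int = 4,
    control_p: float = 0.98,
) -> pd.DataFrame:
    """Simulate per-vial bang-assay survival counts.

    Each fraction gets ``n_vials`` vortexed vials with binomial 24-h survival
    at its fraction's probability (defaults interpolate monotonically from
    0.69 in the bottom to 0.92 in the top fraction), plus unshaken control
    vials with survival probability near 1.  Columns: ``vial, fraction,
    treatment, n_flies, n_alive_24h``.
    """
    p = np.asarray(p_by_fraction, dtype=float)
    if p.shape != (5,) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("p_by_fraction must be 5 probabilities in (0, 1)")
    if not 0 < control_p <= 1:
        raise ValueError("control_p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = (flies_per_vial, flies_per_vial) if isinstance(flies_per_vial, int) else flies_per_vial
    rows = []
    for f in range(5):
        for treatment, nv, pf in (("vortex", n_vials, p[f]),
                                  ("control", n_control_vials, control_p)):
            for v in range(nv):
                nfl = int(rng.integers(lo, hi + 1))
                rows.append(
                    {
                        "vial": f"{FRACTION_NAMES[f]}-{treatment}-{v + 1}",
                        "fraction": f,
                        "treatment": treatment,
                        "n_flies": nfl,
                        "n_alive_24h": int(rng.binomial(nfl, pf)),
                    }
                )
    return pd.DataFrame(rows)
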