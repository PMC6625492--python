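"""Multi-objective Bayesian optimisation over a discrete solvent library.

The selection rule follows Thompson-sampling efficient multi-objective
optimisation (TS-EMO), modified for a discrete candidate set: per repeat, one
posterior function is drawn per objective and evaluated by exhaustive
enumeration over every untested solvent; the candidate maximising the
hypervolume improvement over the current observed Pareto front receives a
vote.  Votes aggregated over repeats bias the suggestion towards
exploitation.  For solvent-mixture campaigns the inner search is a
constrained NSGA-II over (x₁, x₂, x₃, T) with the simplex constraint
Σxᵢ ≤ 1, run batch-sequentially in two steps: the first recipe fixes the
batch temperature, the remaining recipes are chosen at that temperature with
fantasised outcomes conditioning each subsequent draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .descriptors import FeatureSpec, SolventLibrary, featurize
from ._utils import as_seedseq, seed_int
from .errors import (
    ExhaustedLibraryError,
    InvalidArgumentError,
    OracleInterruption,
)
from .surrogate import GPConfig, GPSurrogate, fit_gp, predict, sample_posterior_function

OBJECTIVE_LOWER = np.array([0.0, -100.0])  # conversion %, d.e. %


# --------------------------------------------------------------------------
# Pareto utilities (both objectives maximised)
# --------------------------------------------------------------------------

def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a >= b) and np.any(a > b))


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated objective points with the indices of their sources."""

    points: np.ndarray            # (m, 2), unique, mutually non-dominated
    member_indices: tuple[tuple[int, ...], ...]  # source rows per member

    def __len__(self) -> int:
        return self.points.shape[0]


def pareto_front(points: np.ndarray) -> ParetoFront:
    """Non-dominated subset of objective points (maximisation, 2-D).

    Weakly dominated points are removed; duplicated objective vectors are
    collapsed to a single front member whose provenance lists all source rows.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.size == 0:
        raise InvalidArgumentError("at least one point required")
    if P.shape[1] != 2:
        raise InvalidArgumentError("exactly two objectives supported")
    order = np.lexsort((-P[:, 1], -P[:, 0]))  # obj0 desc, then obj1 desc
    kept: list[int] = []
    best1 = -np.inf
    for i in order:
        if P[i, 1] > best1:
            kept.append(i)
            best1 = P[i, 1]
    # collapse duplicate objective vectors to one member, provenance preserved
    uniq = sorted({(P[i, 0], P[i, 1]) for i in kept}, key=lambda t: (-t[0], -t[1]))
    front_pts = np.array(uniq)
    members = tuple(
        tuple(np.nonzero((P[:, 0] == p[0]) & (P[:, 1] == p[1]))[0].tolist())
        for p in uniq
    )
    return ParetoFront(front_pts, members)


def hypervolume_2d(front: ParetoFront | np.ndarray, reference: Sequence[float]) -> float:
    """Exact dominated hypervolume (staircase area) w.r.t. ``reference``.

    Every front point must dominate the reference point; an empty front has
    hypervolume zero.
    """
    pts = front.points if isinstance(front, ParetoFront) else np.atleast_2d(front)
    ref = np.asarray(reference, dtype=float)
    if pts.size == 0:
        return 0.0
    for p in pts:
        if not _dominates(p, ref):
            raise InvalidArgumentError(
                f"front point {tuple(p)} does not dominate reference {tuple(ref)}"
            )
    order = np.argsort(-pts[:, 0])
    hv = 0.0
    prev_y = ref[1]
    for i in order:
        x, y = pts[i]
        if y > prev_y:
            hv += (x - ref[0]) * (y - prev_y)
            prev_y = y
    return float(hv)


def _hv_clipped(pts: np.ndarray, ref: np.ndarray) -> float:
    """Hypervolume ignoring points that do not dominate the reference."""
    if pts.size == 0:
        return 0.0
    keep = np.all(pts > ref, axis=1)
    if not np.any(keep):
        return 0.0
    P = pts[keep]
    order = np.argsort(-P[:, 0])
    hv, prev_y = 0.0, ref[1]
    for i in order:
        x, y = P[i]
        if y > prev_y:
            hv += (x - ref[0]) * (y - prev_y)
            prev_y = y
    return float(hv)


def default_reference(points: np.ndarray, margin: float = 0.1) -> np.ndarray:
    """Component-wise minimum of observed objectives minus 10% of the range."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = P.min(axis=0), P.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo - margin * span


def hypervolume_improvement(
    candidate: Sequence[float],
    front: ParetoFront | np.ndarray,
    reference: Sequence[float],
) -> float:
    """HV(front ∪ {candidate}) − HV(front); zero iff candidate is dominated."""
    pts = front.points if isinstance(front, ParetoFront) else np.atleast_2d(front)
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    base = hypervolume_2d(pts, ref) if pts.size else 0.0
    joint = pareto_front(np.vstack([pts, cand[None, :]])) if pts.size else pareto_front(cand[None, :])
    return float(hypervolume_2d(joint, ref) - base)


# --------------------------------------------------------------------------
# Campaign state
# --------------------------------------------------------------------------

@dataclass
class CampaignState:
    """Everything the closed loop needs: library, specs, data, surrogates."""

    library: SolventLibrary
    conv_spec: FeatureSpec
    de_spec: FeatureSpec
    experiments: pd.DataFrame   # columns: solvent_id, conversion, de
    gp_config: GPConfig = field(default_factory=GPConfig)
    gp_conv: GPSurrogate | None = None
    gp_de: GPSurrogate | None = None
    reference: np.ndarray = field(default_factory=lambda: OBJECTIVE_LOWER.copy())
    log: list[dict] = field(default_factory=list)

    def __post_init__(self):
        missing = set(self.experiments["solvent_id"]) - set(self.library.ids)
        if missing:
            raise InvalidArgumentError(f"tested ids not in library: {sorted(missing)}")

    @property
    def tested_ids(self) -> list[str]:
        return list(dict.fromkeys(self.experiments["solvent_id"]))

    @property
    def untested_ids(self) -> list[str]:
        tested = set(self.tested_ids)
        return [i for i in self.library.ids if i not in tested]

    def aggregated(self) -> pd.DataFrame:
        """Replicates averaged to one row per solvent (mean objectives)."""
        return (
            self.experiments.groupby("solvent_id", sort=False)[["conversion", "de"]]
            .mean()
            .reset_index()
        )

    def observed_points(self) -> np.ndarray:
        agg = self.aggregated()
        return agg[["conversion", "de"]].to_numpy()

    def refit(self, seed: int | None = 0) -> None:
        agg = self.aggregated()
        recs = [self.library[i] for i in agg["solvent_id"]]
        Xc = featurize(recs, self.conv_spec).to_numpy()
        Xd = featurize(recs, self.de_spec).to_numpy()
        ss = as_seedseq(seed).generate_state(2)
        self.gp_conv = fit_gp(Xc, agg["conversion"].to_numpy(), self.gp_config,
                              seed=int(ss[0] % (2**31)))
        self.gp_de = fit_gp(Xd, agg["de"].to_numpy(), self.gp_config,
                            seed=int(ss[1] % (2**31)))


# --------------------------------------------------------------------------
# Discrete suggestion by exhaustive enumeration
# --------------------------------------------------------------------------

def suggest_discrete(
    state: CampaignState,
    n_repeats: int = 100,
    seed: int | None = 0,
    n_spectral_features: int = 256,
) -> pd.DataFrame:
    """Vote-ranked untested solvents from repeated Thompson-sampling runs.

    Per repeat: draw one posterior function per objective, evaluate both at
    every untested candidate (exhaustive enumeration — no inner genetic
    algorithm is needed on a discrete library), and vote for the candidate
    with the largest hypervolume improvement over the observed front.
    Returns a DataFrame (solvent_id, votes, mean_hvi) sorted by votes, then
    mean HVI, then id; already-tested solvents never appear.
    """
    if state.gp_conv is None or state.gp_de is None:
        raise InvalidArgumentError("surrogates not fitted; call state.refit() first")
    untested = state.untested_ids
    if not untested:
        raise ExhaustedLibraryError("every library solvent has been tested")
    untested = sorted(untested)
    recs = [state.library[i] for i in untested]
    Xc = featurize(recs, state.conv_spec).to_numpy()
    Xd = featurize(recs, state.de_spec).to_numpy()

    obs = state.observed_points()
    front = pareto_front(obs)
    ref = np.asarray(state.reference, dtype=float)
    base_hv = _hv_clipped(front.points, ref)

    votes = np.zeros(len(untested), dtype=int)
    hvi_sums = np.zeros(len(untested))
    ss = as_seedseq(seed).spawn(n_repeats)
    sampled_front_sizes = []
    for r in range(n_repeats):
        s_conv, s_de = ss[r].spawn(2)
        f_conv = sample_posterior_function(
            state.gp_conv, n_spectral_features, seed=s_conv)
        f_de = sample_posterior_function(state.gp_de, n_spectral_features, seed=s_de)
        samp = np.column_stack([f_conv(Xc), f_de(Xd)])
        sampled_front_sizes.append(len(pareto_front(samp)))
        hvi = np.array([
            _hv_clipped(np.vstack([front.points, samp[i][None, :]]), ref) - base_hv
            for i in range(len(untested))
        ])
        winner = int(np.argmax(hvi))  # ties → lowest index = lexicographic id
        votes[winner] += 1
        hvi_sums += hvi
    out = pd.DataFrame(
        {
            "solvent_id": untested,
            "votes": votes,
            "mean_hvi": hvi_sums / n_repeats,
        }
    )
    out = out.sort_values(
        ["votes", "mean_hvi", "solvent_id"], ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out.attrs["sampled_front_sizes"] = sampled_front_sizes
    return out


# --------------------------------------------------------------------------
# Constrained NSGA-II (minimisation)
# --------------------------------------------------------------------------

def _fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    n = F.shape[0]
    dominated_by = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        less = np.all(F[i] <= F, axis=1) & np.any(F[i] < F, axis=1)  # i dominates j
        for j in np.nonzero(less)[0]:
            dominated_by[i].append(j)
        dom_count[i] = int(
            np.sum(np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1))
        )
    fronts = []
    current = np.nonzero(dom_count == 0)[0]
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
    return fronts


def _crowding(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        span = F[order[-1], k] - F[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span
    return dist


def constrained_moo_solve(
    objectives: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    constraint: Callable[[np.ndarray], np.ndarray] | None = None,
    population: int = 60,
    generations: int = 100,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """NSGA-II for two objectives (minimised) with feasibility dominance.

    ``objectives`` maps an (n, d) decision matrix to an (n, 2) objective
    matrix; ``constraint`` returns a violation magnitude per row (0 when
    feasible).  Simulated binary crossover (η=15), polynomial mutation (η=20,
    rate 1/d); infeasible solutions lose tournaments to feasible ones and are
    compared by violation among themselves.  Returns the feasible
    non-dominated decision vectors and their objective values.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] > bounds[:, 1]):
        raise InvalidArgumentError("bounds must be well-formed (lo ≤ hi) pairs")
    if population < 8 or population % 2:
        raise InvalidArgumentError("population must be even and ≥ 8")
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(seed)

    def evaluate(X):
        F = np.atleast_2d(objectives(X))
        G = np.zeros(X.shape[0]) if constraint is None else np.maximum(
            np.asarray(constraint(X), dtype=float), 0.0)
        return F, G

    def rank_population(F, G):
        feas = G <= 0
        rank = np.full(F.shape[0], np.inf)
        crowd = np.zeros(F.shape[0])
        if np.any(feas):
            idx = np.nonzero(feas)[0]
            for fi, fr in enumerate(_fast_non_dominated_sort(F[idx])):
                rank[idx[fr]] = fi
                crowd[idx[fr]] = _crowding(F[idx[fr]])
        return rank, crowd, feas

    def tournament(rank, crowd, feas, G):
        a, b = rng.integers(0, population, 2)
        # feasibility dominance
        if feas[a] != feas[b]:
            return a if feas[a] else b
        if not feas[a]:
            return a if G[a] < G[b] else b
        if rank[a] != rank[b]:
            return a if rank[a] < rank[b] else b
        return a if crowd[a] > crowd[b] else b

    def sbx(p1, p2, eta=15.0, pc=0.9):
        c1, c2 = p1.copy(), p2.copy()
        if rng.random() < pc:
            u = rng.random(d)
            beta = np.where(
                u <= 0.5,
                (2 * u) ** (1 / (eta + 1)),
                (1 / (2 * (1 - u))) ** (1 / (eta + 1)),
            )
            swap = rng.random(d) < 0.5
            beta = np.where(swap, beta, 1.0)
            c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
            c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
        return np.clip(c1, lo, hi), np.clip(c2, lo, hi)

    def mutate(x, eta=20.0):
        y = x.copy()
        do = rng.random(d) < (1.0 / d)
        u = rng.random(d)
        delta = np.where(
            u < 0.5,
            (2 * u) ** (1 / (eta + 1)) - 1,
            1 - (2 * (1 - u)) ** (1 / (eta + 1)),
        )
        y = np.where(do, y + delta * span, y)
        return np.clip(y, lo, hi)

    X = lo + rng.random((population, d)) * span
    F, G = evaluate(X)
    for _ in range(generations):
        rank, crowd, feas = rank_population(F, G)
        children = []
        while len(children) < population:
            i = tournament(rank, crowd, feas, G)
            j = tournament(rank, crowd, feas, G)
            c1, c2 = sbx(X[i], X[j])
            children.append(mutate(c1))
            children.append(mutate(c2))
        Xc = np.array(children[:population])
        Fc, Gc = evaluate(Xc)
        Xall = np.vstack([X, Xc])
        Fall = np.vstack([F, Fc])
        Gall = np.concatenate([G, Gc])
        # environmental selection: feasible first by rank/crowding, then by violation
        feas_all = Gall <= 0
        chosen: list[int] = []
        idx_f = np.nonzero(feas_all)[0]
        if idx_f.size:
            for fr in _fast_non_dominated_sort(Fall[idx_f]):
                ids = idx_f[fr]
                if len(chosen) + len(ids) <= population:
                    chosen.extend(ids.tolist())
                else:
                    cd = _crowding(Fall[ids])
                    order = np.argsort(-cd, kind="stable")
                    need = population - len(chosen)
                    chosen.extend(ids[order[:need]].tolist())
                if len(chosen) >= population:
                    break
        if len(chosen) < population:
            idx_i = np.nonzero(~feas_all)[0]
            order = np.argsort(Gall[idx_i], kind="stable")
            need = population - len(chosen)
            chosen.extend(idx_i[order[:need]].tolist())
        sel = np.array(chosen[:population])
        X, F, G = Xall[sel], Fall[sel], Gall[sel]

    feas = G <= 0
    if not np.any(feas):
        return X[:0], F[:0]
    Xf, Ff = X[feas], F[feas]
    first = _fast_non_dominated_sort(Ff)[0]
    return Xf[first], Ff[first]


# --------------------------------------------------------------------------
# Mixture recipes and two-step batch-sequential selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureBounds:
    """Box bounds for mixture optimisation: fractions in [0, cap], T in °C."""

    temperature: tuple[float, float] = (40.0, 100.0)
    fraction_cap: float = 1.0

    def __post_init__(self):
        if self.temperature[0] > self.temperature[1] or not (0 < self.fraction_cap <= 1):
            raise InvalidArgumentError("infeasible mixture bounds")


@dataclass(frozen=True)
class MixtureRecipe:
    """Volume fractions of three variable solvents + balance, and temperature."""

    x1: float
    x2: float
    x3: float
    temperature_C: float

    def __post_init__(self):
        x = np.array([self.x1, self.x2, self.x3])
        if np.any(x < 0) or x.sum() > 1.0 + 1e-9:
            raise InvalidArgumentError("fractions must be ≥ 0 with Σx ≤ 1")

    @property
    def balance(self) -> float:
        return max(1.0 - (self.x1 + self.x2 + self.x3), 0.0)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3])


@dataclass
class MixtureCampaignState:
    """Mixture/temperature campaign: surrogates on (x₁, x₂, x₃, T) inputs."""

    experiments: pd.DataFrame  # columns: x1, x2, x3, temperature_C, conversion, de
    gp_config: GPConfig = field(default_factory=GPConfig)
    gp_conv: GPSurrogate | None = None
    gp_de: GPSurrogate | None = None
    reference: np.ndarray = field(default_factory=lambda: OBJECTIVE_LOWER.copy())

    def design_matrix(self) -> np.ndarray:
        return self.experiments[["x1", "x2", "x3", "temperature_C"]].to_numpy()

    def observed_points(self) -> np.ndarray:
        return self.experiments[["conversion", "de"]].to_numpy()

    def refit(self, seed: int | None = 0) -> None:
        X = self.design_matrix()
        ss = as_seedseq(seed).generate_state(2)
        self.gp_conv = fit_gp(X, self.experiments["conversion"].to_numpy(),
                              self.gp_config, seed=int(ss[0] % (2**31)))
        self.gp_de = fit_gp(X, self.experiments["de"].to_numpy(),
                            self.gp_config, seed=int(ss[1] % (2**31)))


def _pick_max_hvi(Xset: np.ndarray, Fset: np.ndarray, front_pts: np.ndarray,
                  ref: np.ndarray) -> int:
    base = _hv_clipped(front_pts, ref)
    hvi = np.array([
        _hv_clipped(np.vstack([front_pts, Fset[i][None, :]]), ref) - base
        for i in range(Fset.shape[0])
    ])
    return int(np.argmax(hvi))


def suggest_mixture_batch(
    state: MixtureCampaignState,
    batch_size: int = 5,
    bounds: MixtureBounds = MixtureBounds(),
    seed: int | None = 0,
    population: int = 60,
    generations: int = 60,
    n_spectral_features: int = 256,
) -> list[MixtureRecipe]:
    """Two-step batch-sequential recipe selection.

    Step 1 optimises all four variables (x₁, x₂, x₃, T) and yields recipe 1,
    fixing the batch temperature (parallel reactors share one temperature).
    Step 2 selects the remaining recipes at that temperature, conditioning
    the surrogates on the fantasised (sampled) outcome of each previous
    recipe before drawing the next posterior samples.
    """
    if batch_size < 1:
        raise InvalidArgumentError("batch_size must be ≥ 1")
    if state.gp_conv is None or state.gp_de is None:
        raise InvalidArgumentError("surrogates not fitted; call state.refit() first")
    ref = np.asarray(state.reference, dtype=float)
    front_pts = pareto_front(state.observed_points()).points
    ss = as_seedseq(seed).spawn(batch_size)
    gp_c, gp_d = state.gp_conv, state.gp_de
    cap = bounds.fraction_cap
    recipes: list[MixtureRecipe] = []
    fantasy_pts: list[np.ndarray] = []
    t_fixed: float | None = None
    for b in range(batch_size):
        s_c, s_d, s_ga = ss[b].spawn(3)
        f_c = sample_posterior_function(gp_c, n_spectral_features, seed=s_c)
        f_d = sample_posterior_function(gp_d, n_spectral_features, seed=s_d)
        if b == 0:
            box = [(0.0, cap)] * 3 + [tuple(bounds.temperature)]

            def obj(X):
                return np.column_stack([-f_c(X), -f_d(X)])

            def cons(X):
                return X[:, 0] + X[:, 1] + X[:, 2] - 1.0
        else:
            box = [(0.0, cap)] * 3

            def obj(X, _t=t_fixed):
                Xt = np.column_stack([X, np.full(X.shape[0], _t)])
                return np.column_stack([-f_c(Xt), -f_d(Xt)])

            def cons(X):
                return X.sum(axis=1) - 1.0

        Xp, Fp = constrained_moo_solve(
            obj, box, cons, population=population, generations=generations,
            seed=seed_int(s_ga),
        )
        if Xp.shape[0] == 0:
            raise InvalidArgumentError("optimiser returned no feasible recipe")
        archive = np.vstack([front_pts, *fantasy_pts]) if fantasy_pts else front_pts
        archive = pareto_front(archive).points
        i = _pick_max_hvi(Xp, -Fp, archive, ref)
        if b == 0:
            x1, x2, x3, t_fixed = Xp[i]
        else:
            x1, x2, x3 = Xp[i]
        x_full = np.array([[x1, x2, x3, t_fixed]])
        recipes.append(MixtureRecipe(float(x1), float(x2), float(x3), float(t_fixed)))
        # fantasise the sampled outcome and condition both surrogates on it
        y_c, y_d = float(f_c(x_full)[0]), float(f_d(x_full)[0])
        fantasy_pts.append(np.array([[y_c, y_d]]))
        gp_c = gp_c.condition(x_full, [y_c])
        gp_d = gp_d.condition(x_full, [y_d])
    return recipes


# --------------------------------------------------------------------------
# Closed-loop discrete campaign
# --------------------------------------------------------------------------

def run_campaign(
    state: CampaignState,
    oracle: Callable[[str], tuple[float, float]],
    iterations: int,
    per_iteration: int = 1,
    n_repeats: int = 50,
    seed: int | None = 0,
    n_spectral_features: int = 256,
) -> CampaignState:
    """Suggest → test → refit for ``iterations`` rounds on the discrete library.

    ``oracle`` maps a solvent id to a measured (conversion %, d.e. %) pair —
    either a synthetic ground-truth oracle or a shim that pauses for manual
    data entry.  Each iteration appends the top-voted ``per_iteration``
    untested solvents.  The log records suggestions, votes, the observed
    front, and the hypervolume trajectory against the state's fixed campaign
    reference point (so the trajectory is monotone by construction of the
    growing archive).  On oracle failure the state is left self-consistent
    (all completed iterations appended and refitted) and re-entrant.
    """
    ss = as_seedseq(seed).spawn(max(iterations, 1) + 1)
    if state.gp_conv is None or state.gp_de is None:
        state.refit(seed=seed_int(ss[-1]))
    for it in range(iterations):
        s_sugg, s_fit = ss[it].spawn(2)
        ranked = suggest_discrete(
            state, n_repeats=n_repeats, seed=s_sugg,
            n_spectral_features=n_spectral_features,
        )
        picks = ranked["solvent_id"].head(per_iteration).tolist()
        rows = []
        for sid in picks:
            try:
                conv, de = oracle(sid)
            except Exception as exc:  # checkpoint: state remains consistent
                if rows:
                    state.experiments = pd.concat(
                        [state.experiments, pd.DataFrame(rows)], ignore_index=True)
                    state.refit(seed=seed_int(s_fit))
                raise OracleInterruption(
                    f"oracle failed on {sid!r} at iteration {it}", state) from exc
            rows.append({"solvent_id": sid, "conversion": conv, "de": de})
        state.experiments = pd.concat(
            [state.experiments, pd.DataFrame(rows)], ignore_index=True)
        state.refit(seed=seed_int(s_fit))
        obs = state.observed_points()
        front = pareto_front(obs)
        state.log.append(
            {
                "iteration": len(state.log) + 1,
                "picks": picks,
                "votes": ranked.head(10).to_dict("records"),
                "front": front.points.tolist(),
                "hypervolume": _hv_clipped(front.points, state.reference),
            }
        )
    return state
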