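"""Stochastic Monte Carlo simulator of nucleation-limited Bcl10 filament growth
and autophagosome-mediated degradation.

The model evolves a population of Carma1 nucleation sites, a shared pool of free
Bcl10 monomers, growing filaments, and autophagosomes in discrete synchronous
iterations.  Each iteration applies three phases in order:

1. *Activation* — inactive Carma1 sites become activated through collision with
   the immunological synapse.
2. *Growth* — each activated empty site may nucleate a filament, and each
   growth-enabled filament may gain at most one monomer.  The attachment
   probability switches from ``p_attach`` to ``p_grow`` once the filament has
   crossed the nucleation barrier (``n_barrier`` monomers).
3. *Autophagosome dynamics* — free autophagosomes collide with and attach to
   filaments; attached autophagosomes degrade the filament (end removal or
   interior scission) or fall off.

Monomers are tracked with an exact integer ledger: at every iteration
``free + filamentous + degraded`` equals the initial pool.

The hot loop is compiled with numba; the public API wraps it with small
dataclasses (:class:`SimParams`, :class:`InitDistributions`, :class:`SimCell`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp, xlog1py, xlogy

__all__ = [
    "SimParams",
    "InitDistributions",
    "SimCell",
    "SimTrace",
    "PopulationResult",
    "sample_initial_conditions",
    "growth_pmf",
    "step",
    "run_cell",
    "run_population",
]

RHO_UNDEFINED = np.nan  # sentinel for an undefined correlation

# collision-model codes for the kernel
_COLL_MONOMER_SCALED = 0  # p_coll = min(1, p_collide_bcl10 * free), both phases
_COLL_BARE = 1            # p_coll = p_collide_bcl10, both phases
_COLL_SITE_LIMITED = 2    # pre-barrier bare (site is a small target), post-barrier monomer-scaled
_COLL_MONOMER_POOL = 3    # each free monomer collides w.p. p_collide_bcl10 and
                          # lands on a uniformly chosen site/filament (uncapped)

_ACT_PER_SITE = 0        # every inactive site draws an activation Bernoulli per iteration
_ACT_SINGLE_EVENT = 1    # one collision event per iteration, landing on an inactive site
_ACT_SINGLE_MOLECULE = 2 # one randomly chosen Carma1 oligomer tested per iteration


@dataclass
class SimParams:
    """Probability constants of the simulator.

    All probabilities are per iteration.  ``p_activate``, ``p_attach`` and
    ``p_degrade`` are the variable parameters explored in the analyses; the
    rest are fixed constants motivated by the relative diffusion of Carma1,
    Bcl10 and autophagosomes.
    """

    p_activate: float = 0.5
    p_attach: float = 0.1
    p_grow: float = 0.4
    n_barrier: int = 50
    p_collide_carma: float = 0.1
    p_collide_bcl10: float = 0.01
    p_collide_auto: float = 0.1
    p_attach_auto: float = 0.1
    p_degrade: float = 0.0
    p_detach: float = 0.1
    max_iter: int = 10_000
    punctum_len: int = 50
    collision_model: Literal[
        "monomer_scaled", "bare", "site_limited", "monomer_pool"
    ] = "monomer_pool"
    activation_model: Literal["per_site", "single_event", "single_molecule"] = "single_molecule"
    target_choice: Literal["length_weighted", "uniform"] = "length_weighted"

    def __post_init__(self) -> None:
        for name in (
            "p_activate", "p_attach", "p_grow", "p_collide_carma",
            "p_collide_bcl10", "p_collide_auto", "p_attach_auto",
            "p_degrade", "p_detach",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_barrier < 1:
            raise ValueError("n_barrier must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def _collision_code(self) -> int:
        return {"monomer_scaled": _COLL_MONOMER_SCALED,
                "bare": _COLL_BARE,
                "site_limited": _COLL_SITE_LIMITED,
                "monomer_pool": _COLL_MONOMER_POOL}[self.collision_model]

    @property
    def _activation_code(self) -> int:
        return {"per_site": _ACT_PER_SITE,
                "single_event": _ACT_SINGLE_EVENT,
                "single_molecule": _ACT_SINGLE_MOLECULE}[self.activation_model]


@dataclass
class InitDistributions:
    """Initial-condition distributions for the simulated cell population.

    Nucleation-site and autophagosome counts follow gamma distributions fit to
    imaged cells; the synapse fraction (portion of the cell surface touching
    the activating surface) is normal; the monomer pool is normal around the
    wild-type Bcl10 copy number.  Draws are truncated at zero and counts are
    rounded to integers.
    """

    sites_alpha: float = 1.59
    sites_beta: float = 15.92
    synapse_mu: float = 0.40
    synapse_sigma: float = 0.025
    auto_alpha: float = 4.30
    auto_beta: float = 7.90
    monomers_mu: float = 108_000.0
    monomers_sigma: float = 3_600.0


@dataclass
class SimCell:
    """State of one simulated cell.

    Fixed draws (``n_sites``, ``synapse_fraction``, ``n_autophagosomes``,
    ``initial_monomers``) come from :func:`sample_initial_conditions`; the
    remaining arrays are the evolving state and are allocated lazily on the
    first :func:`step`.
    """

    n_sites: int
    synapse_fraction: float
    n_autophagosomes: int
    initial_monomers: int

    free_monomers: int = field(init=False)
    degraded_monomers: int = field(init=False, default=0)
    site_state: np.ndarray | None = field(init=False, default=None, repr=False)
    site_fil: np.ndarray | None = field(init=False, default=None, repr=False)
    fil_len: np.ndarray | None = field(init=False, default=None, repr=False)
    fil_alive: np.ndarray | None = field(init=False, default=None, repr=False)
    fil_crossed: np.ndarray | None = field(init=False, default=None, repr=False)
    fil_growth: np.ndarray | None = field(init=False, default=None, repr=False)
    fil_site: np.ndarray | None = field(init=False, default=None, repr=False)
    auto_state: np.ndarray | None = field(init=False, default=None, repr=False)
    auto_fil: np.ndarray | None = field(init=False, default=None, repr=False)
    auto_mode: np.ndarray | None = field(init=False, default=None, repr=False)
    auto_pos: np.ndarray | None = field(init=False, default=None, repr=False)
    auto_consuming: np.ndarray | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_sites < 0 or self.n_autophagosomes < 0 or self.initial_monomers < 0:
            raise ValueError("counts must be non-negative")
        self.free_monomers = int(self.initial_monomers)

    capacity_extra: int = field(init=False, default=0)

    @property
    def capacity(self) -> int:
        """Filament-slot capacity (sites + headroom for scission daughters)."""
        return self.n_sites + 4 * self.n_autophagosomes + 16 + self.capacity_extra

    def reset(self) -> None:
        """Discard evolved state, keeping the sampled initial conditions."""
        self.free_monomers = int(self.initial_monomers)
        self.degraded_monomers = 0
        self.site_state = None

    def ensure_state(self) -> None:
        if self.site_state is not None:
            return
        cap = self.capacity
        self.site_state = np.zeros(self.n_sites, dtype=np.int8)
        self.site_fil = np.full(self.n_sites, -1, dtype=np.int64)
        self.fil_len = np.zeros(cap, dtype=np.int64)
        self.fil_alive = np.zeros(cap, dtype=np.bool_)
        self.fil_crossed = np.zeros(cap, dtype=np.bool_)
        self.fil_growth = np.zeros(cap, dtype=np.bool_)
        self.fil_site = np.full(cap, -1, dtype=np.int64)
        na = self.n_autophagosomes
        self.auto_state = np.zeros(na, dtype=np.int8)
        self.auto_fil = np.full(na, -1, dtype=np.int64)
        self.auto_mode = np.zeros(na, dtype=np.int8)
        self.auto_pos = np.zeros(na, dtype=np.int64)
        self.auto_consuming = np.zeros(na, dtype=np.bool_)

    # -- ledger ------------------------------------------------------------
    @property
    def filamentous_monomers(self) -> int:
        if self.fil_len is None:
            return 0
        return int(self.fil_len[self.fil_alive].sum())

    def check_ledger(self) -> None:
        """Exact integer monomer conservation; raises AssertionError on violation."""
        total = self.free_monomers + self.filamentous_monomers + self.degraded_monomers
        assert total == self.initial_monomers, (
            f"monomer ledger violated: {total} != {self.initial_monomers}"
        )

    def puncta_count(self, punctum_len: int = 50) -> int:
        if self.fil_len is None:
            return 0
        ln = self.fil_len[self.fil_alive]
        return int(((ln > 0) & (ln < punctum_len)).sum())


@dataclass
class SimTrace:
    """Per-iteration record of one trial plus the end state."""

    n_iter: int
    free: np.ndarray            # free monomers, length n_iter + 1
    filamentous: np.ndarray     # total monomers in filaments
    degraded: np.ndarray
    n_structures: np.ndarray    # alive filaments with length > 0
    n_puncta: np.ndarray        # alive filaments with 0 < length < punctum_len
    sum_len_puncta: np.ndarray  # monomers inside puncta
    n_attached_autos: np.ndarray
    final_lengths: np.ndarray   # lengths of alive filaments at termination
    initial_monomers: int
    terminated_early: bool

    @property
    def mean_length(self) -> np.ndarray:
        """Per-iteration mean filament length (NaN where no structures)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_structures > 0,
                            self.filamentous / np.maximum(self.n_structures, 1), np.nan)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _alloc_slot(fil_alive):
    for i in range(fil_alive.size):
        if not fil_alive[i]:
            return i
    return -1


@njit(cache=True)
def _step_kernel(
    site_state, site_fil,
    fil_len, fil_alive, fil_crossed, fil_growth, fil_site,
    auto_state, auto_fil, auto_mode, auto_pos, auto_consuming,
    ledger,  # int64[2]: free, degraded
    p_activate, p_attach, p_grow, n_barrier,
    p_collide_carma, p_collide_bcl10, p_collide_auto, p_attach_auto,
    p_degrade, p_detach, synapse_fraction,
    collision_code, activation_code,
    length_weighted,
):
    """One synchronous iteration: activation -> growth -> autophagosome dynamics.

    Returns 0 on success, -1 if a filament slot could not be allocated.
    """
    n_sites = site_state.size
    cap = fil_len.size
    n_auto = auto_state.size

    # --- phase 1: activation ------------------------------------------------
    p_act = p_collide_carma * synapse_fraction * p_activate
    if activation_code == 0:  # per-site
        for s in range(n_sites):
            if site_state[s] == 0 and np.random.random() < p_act:
                site_state[s] = 1
    elif activation_code == 1:  # one collision event per iteration
        if np.random.random() < p_act:
            n_inactive = 0
            for s in range(n_sites):
                if site_state[s] == 0:
                    n_inactive += 1
            if n_inactive > 0:
                k = np.random.randint(n_inactive)
                for s in range(n_sites):
                    if site_state[s] == 0:
                        if k == 0:
                            site_state[s] = 1
                            break
                        k -= 1
    else:  # one randomly chosen Carma1 oligomer tested per iteration
        if n_sites > 0:
            s = np.random.randint(n_sites)
            if site_state[s] == 0 and np.random.random() < p_act:
                site_state[s] = 1

    # --- phase 2: growth ----------------------------------------------------
    if collision_code == 3:
        # pooled collisions: each free monomer collides w.p. p_collide_bcl10
        # and lands on a uniformly chosen target (active empty site or
        # growth-enabled filament); several monomers may attach to the same
        # filament in one iteration.
        n_targets = 0
        targets = np.empty(cap + n_sites, dtype=np.int64)
        for f in range(cap):
            if fil_alive[f] and fil_growth[f]:
                targets[n_targets] = f
                n_targets += 1
        for s in range(n_sites):
            if site_state[s] == 1:
                targets[n_targets] = cap + s
                n_targets += 1
        if n_targets > 0 and ledger[0] > 0:
            n_coll = np.random.binomial(ledger[0], p_collide_bcl10)
            for _ in range(n_coll):
                if ledger[0] <= 0:
                    break
                tgt = targets[np.random.randint(n_targets)]
                if tgt < cap:
                    f = tgt
                    if not (fil_alive[f] and fil_growth[f]):
                        continue
                else:
                    s = tgt - cap
                    if site_state[s] == 2:
                        # site nucleated earlier this iteration; redirect to its filament
                        f = site_fil[s]
                        if f < 0 or not (fil_alive[f] and fil_growth[f]):
                            continue
                    elif site_state[s] == 1:
                        if np.random.random() < p_attach:
                            f = _alloc_slot(fil_alive)
                            if f < 0:
                                return -1
                            fil_alive[f] = True
                            fil_len[f] = 1
                            fil_crossed[f] = n_barrier <= 1
                            fil_growth[f] = True
                            fil_site[f] = s
                            site_state[s] = 2
                            site_fil[s] = f
                            ledger[0] -= 1
                        continue
                    else:
                        continue
                p = p_grow if fil_crossed[f] else p_attach
                if np.random.random() < p:
                    fil_len[f] += 1
                    ledger[0] -= 1
                    if fil_len[f] >= n_barrier:
                        fil_crossed[f] = True
        order = np.empty(0, dtype=np.int64)
    else:
        # capped models: at most one attachment per site/filament per iteration
        order = np.random.permutation(cap + n_sites)
    for idx in order:
        if ledger[0] <= 0:
            break
        if collision_code == 0:
            p_coll_post = min(1.0, p_collide_bcl10 * ledger[0])
            p_coll_pre = p_coll_post
        elif collision_code == 1:
            p_coll_pre = p_collide_bcl10
            p_coll_post = p_collide_bcl10
        else:
            p_coll_pre = p_collide_bcl10
            p_coll_post = min(1.0, p_collide_bcl10 * ledger[0])
        if idx < cap:
            f = idx
            if not (fil_alive[f] and fil_growth[f]):
                continue
            if fil_crossed[f]:
                p = p_coll_post * p_grow
            else:
                p = p_coll_pre * p_attach
            if np.random.random() < p:
                fil_len[f] += 1
                ledger[0] -= 1
                if fil_len[f] >= n_barrier:
                    fil_crossed[f] = True
        else:
            s = idx - cap
            if site_state[s] != 1:
                continue
            if np.random.random() < p_coll_pre * p_attach:
                f = _alloc_slot(fil_alive)
                if f < 0:
                    return -1
                fil_alive[f] = True
                fil_len[f] = 1
                fil_crossed[f] = n_barrier <= 1
                fil_growth[f] = True
                fil_site[f] = s
                site_state[s] = 2
                site_fil[s] = f
                ledger[0] -= 1

    # --- phase 3: autophagosome dynamics -------------------------------------
    if n_auto > 0:
        aorder = np.random.permutation(n_auto)
        for a in aorder:
            if auto_state[a] == 0:
                # free: collide with a filament, then attach
                total_len = 0
                n_alive = 0
                for f in range(cap):
                    if fil_alive[f] and fil_len[f] > 0:
                        total_len += fil_len[f]
                        n_alive += 1
                if n_alive == 0:
                    continue
                if np.random.random() >= p_collide_auto:
                    continue
                # choose target filament
                target = -1
                if length_weighted:
                    r = np.random.random() * total_len
                    acc = 0.0
                    for f in range(cap):
                        if fil_alive[f] and fil_len[f] > 0:
                            acc += fil_len[f]
                            if r < acc:
                                target = f
                                break
                    if target < 0:
                        target = cap - 1
                else:
                    k = np.random.randint(n_alive)
                    for f in range(cap):
                        if fil_alive[f] and fil_len[f] > 0:
                            if k == 0:
                                target = f
                                break
                            k -= 1
                if np.random.random() < p_attach_auto:
                    L = fil_len[target]
                    pos = 1 + np.random.randint(L)
                    auto_state[a] = 1
                    auto_fil[a] = target
                    auto_pos[a] = pos
                    auto_mode[a] = 0 if pos == L else 1
                    auto_consuming[a] = False
            else:
                f = auto_fil[a]
                # stale attachment (filament removed earlier this iteration)
                if f < 0 or not fil_alive[f] or fil_len[f] <= 0:
                    auto_state[a] = 0
                    auto_fil[a] = -1
                    auto_consuming[a] = False
                    continue
                if auto_consuming[a]:
                    # consuming daughter 2: never detaches until fully degraded
                    if np.random.random() < p_degrade:
                        fil_len[f] -= 1
                        ledger[1] += 1
                        if fil_len[f] == 0:
                            fil_alive[f] = False
                            auto_state[a] = 0
                            auto_fil[a] = -1
                            auto_consuming[a] = False
                    continue
                if auto_mode[a] == 0:
                    # end attachment: remove one monomer from the free end
                    if np.random.random() < p_degrade:
                        fil_len[f] -= 1
                        ledger[1] += 1
                        L = fil_len[f]
                        if L == 0:
                            fil_alive[f] = False
                            s = fil_site[f]
                            if s >= 0:
                                site_state[s] = 1  # site reverts to active-nucleating
                                site_fil[s] = -1
                            fil_site[f] = -1
                            auto_state[a] = 0
                            auto_fil[a] = -1
                        else:
                            # clamp interior attachments that pointed past the new end
                            for b in range(n_auto):
                                if b != a and auto_state[b] == 1 and auto_fil[b] == f:
                                    if auto_pos[b] > L:
                                        auto_pos[b] = L
                                        auto_mode[b] = 0
                    elif np.random.random() < p_detach:
                        auto_state[a] = 0
                        auto_fil[a] = -1
                else:
                    # interior attachment: scission on a degradation event
                    if np.random.random() < p_degrade:
                        L = fil_len[f]
                        p = auto_pos[a]
                        if p > L:
                            p = L
                        d2 = _alloc_slot(fil_alive)
                        if d2 < 0:
                            return -1
                        # daughter 2: autophagosome side, consumed monomer by monomer
                        fil_alive[d2] = True
                        fil_len[d2] = L - p + 1
                        fil_crossed[d2] = fil_crossed[f]
                        fil_growth[d2] = False
                        fil_site[d2] = -1
                        # daughter 1: nucleation-site side, stable, growth disabled
                        fil_len[f] = p - 1
                        fil_growth[f] = False
                        if fil_len[f] == 0:
                            fil_alive[f] = False
                            s = fil_site[f]
                            if s >= 0:
                                site_state[s] = 1
                                site_fil[s] = -1
                            fil_site[f] = -1
                        auto_fil[a] = d2
                        auto_mode[a] = 0
                        auto_pos[a] = fil_len[d2]
                        auto_consuming[a] = True
                        # re-home the other autophagosomes attached to f
                        for b in range(n_auto):
                            if b != a and auto_state[b] == 1 and auto_fil[b] == f:
                                if auto_pos[b] >= p:
                                    auto_fil[b] = d2
                                    auto_pos[b] = auto_pos[b] - p + 1
                                    auto_mode[b] = 0 if auto_pos[b] >= fil_len[d2] else 1
                                elif not fil_alive[f]:
                                    auto_state[b] = 0
                                    auto_fil[b] = -1
                                else:
                                    auto_mode[b] = 0 if auto_pos[b] >= fil_len[f] else 1
                    elif np.random.random() < p_detach:
                        auto_state[a] = 0
                        auto_fil[a] = -1
    return 0


@njit(cache=True)
def _run_trial_kernel(
    site_state, site_fil,
    fil_len, fil_alive, fil_crossed, fil_growth, fil_site,
    auto_state, auto_fil, auto_mode, auto_pos, auto_consuming,
    ledger,
    p_activate, p_attach, p_grow, n_barrier,
    p_collide_carma, p_collide_bcl10, p_collide_auto, p_attach_auto,
    p_degrade, p_detach, synapse_fraction,
    collision_code, activation_code, length_weighted,
    growth_only, max_iter, punctum_len,
    record,
    rec_free, rec_fil, rec_deg, rec_nstruct, rec_npunc, rec_lenpunc, rec_natt,
    seed,
):
    """Run one trial to termination.  Returns (n_iter, status)."""
    np.random.seed(seed)
    cap = fil_len.size
    n_auto = auto_state.size

    if record:
        rec_free[0] = ledger[0]
        rec_fil[0] = 0
        rec_deg[0] = ledger[1]
        rec_nstruct[0] = 0
        rec_npunc[0] = 0
        rec_lenpunc[0] = 0
        rec_natt[0] = 0

    t = 0
    while t < max_iter:
        status = _step_kernel(
            site_state, site_fil,
            fil_len, fil_alive, fil_crossed, fil_growth, fil_site,
            auto_state, auto_fil, auto_mode, auto_pos, auto_consuming,
            ledger,
            p_activate, p_attach, p_grow, n_barrier,
            p_collide_carma, p_collide_bcl10, p_collide_auto, p_attach_auto,
            p_degrade, p_detach, synapse_fraction,
            collision_code, activation_code, length_weighted,
        )
        if status != 0:
            return t, status
        t += 1

        filamentous = 0
        nstruct = 0
        npunc = 0
        lenpunc = 0
        for f in range(cap):
            if fil_alive[f] and fil_len[f] > 0:
                filamentous += fil_len[f]
                nstruct += 1
                if fil_len[f] < punctum_len:
                    npunc += 1
                    lenpunc += fil_len[f]
        if record:
            natt = 0
            for a in range(n_auto):
                if auto_state[a] == 1:
                    natt += 1
            rec_free[t] = ledger[0]
            rec_fil[t] = filamentous
            rec_deg[t] = ledger[1]
            rec_nstruct[t] = nstruct
            rec_npunc[t] = npunc
            rec_lenpunc[t] = lenpunc
            rec_natt[t] = natt

        if growth_only:
            if ledger[0] <= 0:
                return t, 0
        else:
            if ledger[0] + filamentous <= 0:
                return t, 0
    return t, 1  # max_iter reached


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def sample_initial_conditions(
    dists: InitDistributions,
    wild_type: bool = True,
    seed: int | np.random.Generator | None = None,
) -> SimCell:
    """Draw one cell's initial conditions.

    ``wild_type=False`` scales the monomer pool 5x up toward the overexpressing
    line; the analyses in this package use the wild-type pool throughout.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_sites = int(round(max(0.0, rng.gamma(dists.sites_alpha, dists.sites_beta))))
    synapse = float(min(1.0, max(0.0, rng.normal(dists.synapse_mu, dists.synapse_sigma))))
    n_auto = int(round(max(0.0, rng.gamma(dists.auto_alpha, dists.auto_beta))))
    mu = dists.monomers_mu if wild_type else 5.0 * dists.monomers_mu
    sigma = dists.monomers_sigma if wild_type else 5.0 * dists.monomers_sigma
    monomers = int(round(max(0.0, rng.normal(mu, sigma))))
    return SimCell(
        n_sites=n_sites,
        synapse_fraction=synapse,
        n_autophagosomes=n_auto,
        initial_monomers=monomers,
    )


def growth_pmf(n: int, x: int | np.ndarray, L0: int, p_attach: float, p_grow: float):
    """Probability that a filament has length ``x`` after ``n`` attachment
    attempts under two-phase nucleation-limited growth.

    Below the nucleation barrier ``L0`` the length is binomial in ``p_attach``;
    at or above it the pmf convolves the barrier-crossing iteration (negative
    binomial in ``p_attach``) with post-barrier binomial growth in ``p_grow``.
    Computed in log space for numerical stability.
    """
    if not (0.0 <= p_attach <= 1.0 and 0.0 <= p_grow <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if L0 < 1:
        raise ValueError("L0 must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    xs = np.atleast_1d(np.asarray(x, dtype=np.int64))
    out = np.zeros(xs.shape, dtype=np.float64)

    def _log_binom(nn, kk, pp):
        # log C(nn, kk) p^k (1-p)^(n-k); xlogy/xlog1py give 0*log(0) == 0
        nn = np.asarray(nn, dtype=np.float64)
        kk = np.asarray(kk, dtype=np.float64)
        lc = gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)
        return lc + xlogy(kk, pp) + xlog1py(nn - kk, -pp)

    for j, xv in enumerate(xs):
        if xv < 0 or xv > n:
            out[j] = 0.0
        elif xv < L0:
            out[j] = np.exp(_log_binom(n, xv, p_attach))
        else:
            k = xv - L0  # post-barrier growth count
            i = np.arange(L0, n - k + 1)  # iteration of the L0-th attachment
            if i.size == 0:
                out[j] = 0.0
                continue
            log_cross = _log_binom(i - 1, L0 - 1, p_attach)
            # the L0-th success itself
            log_cross = log_cross + (np.log(p_attach) if p_attach > 0 else -np.inf)
            # classic negative-binomial pmf is C(i-1, L0-1) p^L0 q^(i-L0);
            # _log_binom(i-1, L0-1, p) already contributes p^(L0-1) q^(i-L0)
            log_post = _log_binom(n - i, k, p_grow)
            out[j] = np.exp(logsumexp(log_cross + log_post))
    return out if np.ndim(x) else float(out[0])


def _kernel_args(cell: SimCell, params: SimParams):
    cell.ensure_state()
    ledger = np.array([cell.free_monomers, cell.degraded_monomers], dtype=np.int64)
    return ledger, (
        cell.site_state, cell.site_fil,
        cell.fil_len, cell.fil_alive, cell.fil_crossed, cell.fil_growth, cell.fil_site,
        cell.auto_state, cell.auto_fil, cell.auto_mode, cell.auto_pos, cell.auto_consuming,
        ledger,
        params.p_activate, params.p_attach, params.p_grow, params.n_barrier,
        params.p_collide_carma, params.p_collide_bcl10,
        params.p_collide_auto, params.p_attach_auto,
        params.p_degrade, params.p_detach, cell.synapse_fraction,
        params._collision_code, params._activation_code,
        params.target_choice == "length_weighted",
    )


def step(cell: SimCell, params: SimParams, rng_seed: int) -> SimCell:
    """Apply one synchronous iteration in place.  ``rng_seed`` seeds the
    kernel RNG for this iteration (determinism contract)."""
    ledger, args = _kernel_args(cell, params)
    _seed_kernel(rng_seed & 0x7FFFFFFF)
    status = _step_kernel(*args)
    if status != 0:
        raise RuntimeError("filament slot capacity exhausted")
    cell.free_monomers = int(ledger[0])
    cell.degraded_monomers = int(ledger[1])
    cell.check_ledger()
    return cell


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


def run_cell(
    cell: SimCell,
    params: SimParams,
    seed: int,
    growth_only: bool = False,
    record: bool = True,
    max_iter: int | None = None,
) -> SimTrace:
    """Run one trial to termination.

    Growth-only mode terminates when the free monomer pool is exhausted;
    growth+degradation mode stops after ``max_iter`` iterations or when all
    monomeric and filamentous Bcl10 is gone, whichever comes first.
    """
    if max_iter is None:
        # growth-only runs need headroom to reach full monomer conversion
        max_iter = params.max_iter if not growth_only else max(params.max_iter, 400_000)
    n_rec = max_iter + 1 if record else 1
    # scission orphans can exceed the default slot headroom; deterministically
    # rerun the trial with doubled capacity until it fits
    for _attempt in range(8):
        ledger, args = _kernel_args(cell, params)
        rec = [np.zeros(n_rec, dtype=np.int64) for _ in range(7)]
        n_iter, status = _run_trial_kernel(
            *args,
            growth_only, max_iter, params.punctum_len,
            record,
            *rec,
            seed & 0x7FFFFFFF,
        )
        if status >= 0:
            break
        cell.reset()
        cell.capacity_extra = max(256, 2 * cell.capacity_extra)
    else:
        raise RuntimeError("filament slot capacity exhausted")
    cell.free_monomers = int(ledger[0])
    cell.degraded_monomers = int(ledger[1])
    cell.check_ledger()
    final_lengths = np.sort(cell.fil_len[cell.fil_alive & (cell.fil_len > 0)])[::-1].copy()
    sl = slice(0, n_iter + 1)
    return SimTrace(
        n_iter=n_iter,
        free=rec[0][sl], filamentous=rec[1][sl], degraded=rec[2][sl],
        n_structures=rec[3][sl], n_puncta=rec[4][sl], sum_len_puncta=rec[5][sl],
        n_attached_autos=rec[6][sl],
        final_lengths=final_lengths,
        initial_monomers=cell.initial_monomers,
        terminated_early=(status == 0),
    )


@dataclass
class PopulationResult:
    """Summary of a population run (same cells reused across configurations)."""

    params: SimParams
    n_cells: int
    n_trials: int
    growth_only: bool
    # per-cell end-state summaries (trials pooled)
    puncta_count: np.ndarray        # mean end-state puncta per trial
    mean_filament_length: np.ndarray
    n_sites: np.ndarray
    n_autophagosomes: np.ndarray
    rho_end: float                  # Pearson(puncta count, mean filament length)
    # over-time population summaries (degradation mode; empty in growth mode)
    rho_t: np.ndarray
    rho_t_n: np.ndarray             # number of cell-trial points behind each rho_t
    mean_concentration: np.ndarray  # population mean filamentous monomers, normalised to max
    peak_concentration: float       # raw peak of the population mean (monomers)
    n_max: np.ndarray               # per-cell mean iteration of peak filamentous concentration
    n_half: np.ndarray              # per-cell mean iteration of first half-decay (NaN if not reached)
    cumulative_lengths: np.ndarray  # pooled end-state filament lengths


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return RHO_UNDEFINED
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def sample_population(
    dists: InitDistributions,
    n_cells: int,
    seed: int,
    wild_type: bool = True,
) -> list[SimCell]:
    """Sample the heterogeneous cell population once, for reuse across
    parameter configurations."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE11]))
    return [sample_initial_conditions(dists, wild_type=wild_type, seed=rng)
            for _ in range(n_cells)]


def run_population(
    params: SimParams,
    dists: InitDistributions | None = None,
    n_cells: int = 100,
    n_trials: int = 10,
    seed: int = 0,
    growth_only: bool = False,
    wild_type: bool = True,
    cells: list[SimCell] | None = None,
    punctum_fraction_mode: Literal["structures", "monomers"] = "structures",
    mean_length_mode: Literal["all", "non_punctate"] = "all",
    rho_t_mode: Literal["cell_mean", "pooled"] = "cell_mean",
    max_iter: int | None = None,
) -> PopulationResult:
    """Simulate ``n_cells`` heterogeneous cells, ``n_trials`` trials each.

    End-state rho is the Pearson correlation across cells between the mean
    per-trial puncta count and the pooled mean filament length.  In
    growth+degradation mode the over-time correlation rho(t) between the
    punctate fraction and the mean filament length is accumulated across all
    cell-trial pairs still running at iteration t.
    """
    if n_cells < 1 or n_trials < 1:
        raise ValueError("n_cells and n_trials must be >= 1")
    dists = dists or InitDistributions()
    if cells is None:
        cells = sample_population(dists, n_cells, seed, wild_type=wild_type)
    if max_iter is None:
        max_iter = params.max_iter if not growth_only else max(params.max_iter, 400_000)
    record = not growth_only

    T = max_iter + 1 if record else 1
    acc = {k: np.zeros(T) for k in ("n", "sx", "sy", "sxy", "sxx", "syy")}
    conc_sum = np.zeros(T)
    conc_n = np.zeros(T)

    puncta = np.zeros(n_cells)
    mean_len = np.full(n_cells, np.nan)
    n_sites = np.zeros(n_cells, dtype=int)
    n_autos = np.zeros(n_cells, dtype=int)
    n_max = np.full(n_cells, np.nan)
    n_half = np.full(n_cells, np.nan)
    all_lengths: list[np.ndarray] = []

    for ci, proto in enumerate(cells):
        n_sites[ci] = proto.n_sites
        n_autos[ci] = proto.n_autophagosomes
        cell_puncta = np.zeros(n_trials)
        cell_lengths: list[np.ndarray] = []
        cell_nmax = np.full(n_trials, np.nan)
        cell_nhalf = np.full(n_trials, np.nan)
        if record:
            cx = np.zeros(T)
            cy = np.zeros(T)
            cn = np.zeros(T)
        for ti in range(n_trials):
            cell = SimCell(
                n_sites=proto.n_sites,
                synapse_fraction=proto.synapse_fraction,
                n_autophagosomes=proto.n_autophagosomes if not growth_only else 0,
                initial_monomers=proto.initial_monomers,
            )
            tseed = int(np.random.SeedSequence([seed, ci, ti, 0x51]).generate_state(1)[0]
                        & 0x7FFFFFFF)
            trace = run_cell(cell, params, tseed, growth_only=growth_only,
                             record=record, max_iter=max_iter)
            cell_puncta[ti] = cell.puncta_count(params.punctum_len)
            cell_lengths.append(trace.final_lengths)
            if record:
                t_end = trace.n_iter + 1
                ns = trace.n_structures[:t_end].astype(float)
                ok = ns > 0
                if punctum_fraction_mode == "structures":
                    x = np.where(ok, trace.n_puncta[:t_end] / np.maximum(ns, 1), 0.0)
                else:
                    fil = np.maximum(trace.filamentous[:t_end], 1)
                    x = np.where(ok, trace.sum_len_puncta[:t_end] / fil, 0.0)
                y = np.where(ok, trace.filamentous[:t_end] / np.maximum(ns, 1), 0.0)
                idx = np.nonzero(ok)[0]
                if rho_t_mode == "pooled":
                    acc["n"][idx] += 1
                    acc["sx"][idx] += x[idx]
                    acc["sy"][idx] += y[idx]
                    acc["sxy"][idx] += x[idx] * y[idx]
                    acc["sxx"][idx] += x[idx] ** 2
                    acc["syy"][idx] += y[idx] ** 2
                else:
                    cx[idx] += x[idx]
                    cy[idx] += y[idx]
                    cn[idx] += 1
                conc_sum[:t_end] += trace.filamentous[:t_end]
                conc_n[:t_end] += 1
                fil_tr = trace.filamentous[:t_end]
                if fil_tr.size and fil_tr.max() > 0:
                    imax = int(np.argmax(fil_tr))
                    cell_nmax[ti] = imax
                    half = fil_tr.max() / 2.0
                    after = np.nonzero(fil_tr[imax:] <= half)[0]
                    if after.size:
                        cell_nhalf[ti] = imax + int(after[0])
        puncta[ci] = cell_puncta.mean()
        pooled = np.concatenate(cell_lengths) if cell_lengths else np.empty(0)
        if mean_length_mode == "non_punctate":
            non_punc = pooled[pooled >= params.punctum_len]
            pooled_for_mean = non_punc if non_punc.size else pooled
        else:
            pooled_for_mean = pooled
        if pooled_for_mean.size:
            mean_len[ci] = pooled_for_mean.mean()
        all_lengths.append(pooled)
        if record:
            n_max[ci] = np.nanmean(cell_nmax) if np.any(np.isfinite(cell_nmax)) else np.nan
            n_half[ci] = np.nanmean(cell_nhalf) if np.any(np.isfinite(cell_nhalf)) else np.nan
            if rho_t_mode == "cell_mean":
                idx = np.nonzero(cn > 0)[0]
                xm = cx[idx] / cn[idx]
                ym = cy[idx] / cn[idx]
                acc["n"][idx] += 1
                acc["sx"][idx] += xm
                acc["sy"][idx] += ym
                acc["sxy"][idx] += xm * ym
                acc["sxx"][idx] += xm ** 2
                acc["syy"][idx] += ym ** 2

    rho_end = _pearson(puncta, mean_len)

    if record:
        n = acc["n"]
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = acc["sxy"] - acc["sx"] * acc["sy"] / np.maximum(n, 1)
            vx = acc["sxx"] - acc["sx"] ** 2 / np.maximum(n, 1)
            vy = acc["syy"] - acc["sy"] ** 2 / np.maximum(n, 1)
            rho_t = np.where((n >= 10) & (vx > 0) & (vy > 0),
                             cov / np.sqrt(np.maximum(vx * vy, 1e-300)), np.nan)
            mean_conc = np.where(conc_n > 0, conc_sum / np.maximum(conc_n, 1), np.nan)
        if np.any(np.isfinite(mean_conc)) and np.nanmax(mean_conc) > 0:
            peak_conc = float(np.nanmax(mean_conc))
            mean_conc = mean_conc / peak_conc
        else:
            peak_conc = 0.0
    else:
        rho_t = np.empty(0)
        n = np.empty(0)
        mean_conc = np.empty(0)
        peak_conc = np.nan

    return PopulationResult(
        params=params, n_cells=n_cells, n_trials=n_trials, growth_only=growth_only,
        puncta_count=puncta, mean_filament_length=mean_len,
        n_sites=n_sites, n_autophagosomes=n_autos,
        rho_end=rho_end,
        rho_t=rho_t, rho_t_n=n if record else np.empty(0),
        mean_concentration=mean_conc,
        peak_concentration=peak_conc,
        n_max=n_max, n_half=n_half,
        cumulative_lengths=np.concatenate(all_lengths) if all_lengths else np.empty(0),
    )


def plateau_rho(rho_t: np.ndarray, window: int = 301, min_dwell: int = 500):
    """Smoothed minimum of rho(t) and the dwell time at or below -0.6.

    Returns ``(plateau_value, dwell_iterations)`` where ``plateau_value`` is
    the minimum of a centered moving average of rho(t) and ``dwell_iterations``
    counts smoothed iterations at or below -0.6 (the experimentally observed
    band's upper edge).
    """
    ok = np.isfinite(rho_t)
    if ok.sum() < window:
        return np.nan, 0
    idx = np.nonzero(ok)[0]
    vals = rho_t[idx]
    kernel = np.ones(window) / window
    sm = np.convolve(vals, kernel, mode="valid")
    return float(sm.min()), int((sm <= -0.6).sum())
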