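"""Goldman–Yang codon substitution core.

The model: a 61-state continuous-time Markov chain over the sense codons
of the universal code.  Instantaneous rates for single-nucleotide changes
are ``pi_j * kappa^[transition] * omega^[nonsynonymous]``; multi-nucleotide
changes are forbidden.  The generator is scaled so one unit of branch
length is one expected codon substitution.  Site-class mixtures (M0, M1a,
M2a, M7, M8), branch-partition omegas (two-ratio clade models) and a
free-ratio model (one omega per branch) all share the same pruning
likelihood and quasi-Newton fitting machinery.

omega = dN/dS is the selective-pressure ratio: <1 purifying selection,
1 neutrality, >1 positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import expm

from .seqio import CODONS, CODON_AA, CodonAlignment
from .trees import Phylogeny

__all__ = [
    "CodonModelSpec", "SiteMixtureSpec", "FitResult",
    "codon_frequencies", "build_rate_matrix", "transition_probabilities",
    "log_likelihood", "fit", "branch_expected_subs", "choose_frequency_model",
]

N_STATES = 61

# ---------------------------------------------------------------- static
# single-nucleotide-change structure of the sense-codon state space

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_structure():
    i_idx, j_idx, is_ts, is_syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            i_idx.append(i)
            j_idx.append(j)
            is_ts.append(diff[0] in _TRANSITIONS)
            is_syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(i_idx), np.array(j_idx),
        np.array(is_ts, dtype=bool), np.array(is_syn, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _pair_structure()

_NT_INDEX = {b: k for k, b in enumerate("ACGT")}
_CODON_NTS = np.array([[_NT_INDEX[b] for b in c] for c in CODONS])  # (61, 3)


# ------------------------------------------------------------- frequencies

def codon_frequencies(alignment: CodonAlignment, model: str = "F3X4") -> np.ndarray:
    """Equilibrium codon frequencies from the data.

    ``equal``: uniform 1/61.  ``F1X4``: products of pooled nucleotide
    frequencies.  ``F3X4``: products of position-specific nucleotide
    frequencies.  ``F61``: observed codon counts with add-one smoothing.
    All renormalised over the 61 sense codons.
    """
    codes = alignment.codes
    observed = codes[codes >= 0]
    if model == "equal":
        freqs = np.full(N_STATES, 1.0 / N_STATES)
    elif model == "F61":
        counts = np.bincount(observed, minlength=N_STATES).astype(float) + 1.0
        freqs = counts / counts.sum()
    elif model in ("F1X4", "F3X4"):
        nt_counts = np.zeros((3, 4))
        for pos in range(3):
            pos_nts = _CODON_NTS[observed, pos]
            nt_counts[pos] += np.bincount(pos_nts, minlength=4)
        nt_counts += 1.0  # smoothing: never a zero frequency
        if model == "F1X4":
            pooled = nt_counts.sum(axis=0)
            nt_freqs = np.tile(pooled / pooled.sum(), (3, 1))
        else:
            nt_freqs = nt_counts / nt_counts.sum(axis=1, keepdims=True)
        freqs = (
            nt_freqs[0, _CODON_NTS[:, 0]]
            * nt_freqs[1, _CODON_NTS[:, 1]]
            * nt_freqs[2, _CODON_NTS[:, 2]]
        )
        freqs = freqs / freqs.sum()
    else:
        raise ValueError(f"unknown frequency model {model!r}")
    return freqs


# ------------------------------------------------------------------ specs

@dataclass
class SiteMixtureSpec:
    """Site-class mixture over omega.

    ``classes`` are explicit (proportion, omega) pairs; ``beta`` adds a
    beta(p, q) component of total weight ``beta_weight`` discretised into
    ``ncat`` equal-probability categories represented by their medians.
    """

    model_id: str
    classes: list[tuple[float, float]] = field(default_factory=list)
    beta: tuple[float, float] | None = None
    beta_weight: float = 0.0
    ncat: int = 10

    def categories(self) -> tuple[np.ndarray, np.ndarray]:
        """Expanded (weights, omegas) of the full mixture."""
        weights = [p for p, _ in self.classes]
        omegas = [w for _, w in self.classes]
        if self.beta is not None and self.beta_weight > 0:
            p, q = self.beta
            qs = (np.arange(self.ncat) + 0.5) / self.ncat
            cats = stats.beta.ppf(qs, p, q)
            weights = list(np.full(self.ncat, self.beta_weight / self.ncat)) + weights
            omegas = list(cats) + omegas
        w = np.asarray(weights, dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError(f"mixture proportions sum to {w.sum()}, not 1")
        return w, np.asarray(omegas, dtype=float)

    def mean_omega(self) -> float:
        w, om = self.categories()
        return float(w @ om)


@dataclass
class CodonModelSpec:
    """kappa, codon frequencies and the omega structure of one model.

    ``omega_structure`` is a scalar (single ratio), a mapping branch-id ->
    omega (branch partition / free ratio), or a :class:`SiteMixtureSpec`.
    """

    kappa: float
    freqs: np.ndarray
    omega_structure: float | Mapping[int, float] | SiteMixtureSpec
    freq_model: str = "F3X4"

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (N_STATES,) or np.any(f <= 0) or not np.isclose(f.sum(), 1):
            raise ValueError("freqs must be 61 positive values summing to 1")
        self.freqs = f / f.sum()


@dataclass
class FitResult:
    """A maximum-likelihood fit: lnL, MLEs and the per-branch table."""

    model_id: str
    lnL: float
    spec: CodonModelSpec
    params: dict[str, float]
    branch_lengths: np.ndarray           # per node id (root entry unused)
    branch_table: pd.DataFrame           # branch, t, omega, dN, dS
    n_params: int
    converged: bool
    tree: Phylogeny
    foreground: set[int] | None = None


# ---------------------------------------------------------------- matrices

def build_rate_matrix(spec: CodonModelSpec, omega: float) -> np.ndarray:
    """Scaled GY-style generator for a single omega.

    Rows sum to zero; scaling sets sum_i pi_i * (-q_ii) = 1 so branch
    lengths are expected substitutions per codon.
    """
    return _rate_matrix(spec.kappa, spec.freqs, omega)


def _rate_matrix(kappa: float, freqs: np.ndarray, omega: float) -> np.ndarray:
    if omega < 0:
        raise ValueError("omega must be >= 0")
    Q = np.zeros((N_STATES, N_STATES))
    rates = freqs[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0)
    rates = rates * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = rates
    Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
    scale = -(freqs @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    return expm(Q * t)


class _EigGenerator:
    """Spectral form of a reversible scaled generator for fast P(t).

    Symmetrise S = D^{1/2} Q D^{-1/2} (D = diag(pi)), eigendecompose once,
    then P(t) = D^{-1/2} V exp(L t) V' D^{1/2} for any t.
    """

    def __init__(self, kappa: float, freqs: np.ndarray, omega: float):
        Q = _rate_matrix(kappa, freqs, omega)
        sq = np.sqrt(freqs)
        S = (Q / sq[None, :]) * sq[:, None]
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        self.lam = lam
        self.left = V / sq[:, None]          # D^{-1/2} V
        self.right = V.T * sq[None, :]       # V' D^{1/2}

    def P(self, t: float) -> np.ndarray:
        M = (self.left * np.exp(self.lam * t)[None, :]) @ self.right
        np.maximum(M, 0.0, out=M)
        return M


# ------------------------------------------------------------- likelihood

def _compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their multiplicities."""
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(float)


def _prune_class(
    patterns: np.ndarray,
    tree: Phylogeny,
    freqs: np.ndarray,
    Ps: dict[int, np.ndarray],
    tip_row: dict[int, int],
) -> np.ndarray:
    """Per-pattern log-likelihood for one site class (Felsenstein pruning).

    ``patterns`` is (n_taxa, n_pat) with -1 for missing/ambiguous states
    (summed over all 61 codons); ``Ps`` maps branch (child-node id) to its
    transition matrix; ``tip_row`` maps tip node id -> pattern row.
    Log-space scaling guards against underflow.
    """
    n_pat = patterns.shape[1]
    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_pat)
    for node in tree.postorder:
        if not tree.children[node]:
            continue
        L = np.ones((N_STATES, n_pat))
        for child in tree.children[node]:
            P = Ps[child]
            if not tree.children[child]:
                states = patterns[tip_row[child]]
                contrib = np.ones((N_STATES, n_pat))
                resolved = states >= 0
                contrib[:, resolved] = P[:, states[resolved]]
            else:
                contrib = P @ partial.pop(child)
            L *= contrib
        m = L.max(axis=0)
        m[m == 0] = 1.0
        L /= m
        log_scale += np.log(m)
        partial[node] = L
    root_lik = freqs @ partial[tree.root]
    return np.log(np.maximum(root_lik, 1e-300)) + log_scale


def _site_logliks(
    patterns: np.ndarray,
    taxa: list[str],
    tree: Phylogeny,
    kappa: float,
    freqs: np.ndarray,
    class_weights: np.ndarray,
    class_branch_omegas: np.ndarray,
    branch_lengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mixture per-pattern log-likelihoods.

    ``class_branch_omegas`` is (n_class, n_nodes): the omega acting on each
    branch within each site class (site models repeat one omega across
    branches; partition models have a single class with branch-varying
    omega).  Returns (mixture lnL per pattern, per-class matrix).
    """
    tip_row = {tree.tip_index[t]: r for r, t in enumerate(taxa)}
    n_class = class_weights.shape[0]
    eig_cache: dict[float, _EigGenerator] = {}
    per_class = np.empty((n_class, patterns.shape[1]))
    branch_ids = tree.branch_ids()
    for k in range(n_class):
        Ps = {}
        for b in branch_ids:
            om = float(class_branch_omegas[k, b])
            if om not in eig_cache:
                eig_cache[om] = _EigGenerator(kappa, freqs, om)
            Ps[b] = eig_cache[om].P(float(branch_lengths[b]))
        per_class[k] = _prune_class(patterns, tree, freqs, Ps, tip_row)
    if n_class == 1:
        return per_class[0], per_class
    logw = np.log(class_weights)[:, None]
    mix = per_class + logw
    m = mix.max(axis=0)
    site = m + np.log(np.exp(mix - m).sum(axis=0))
    return site, per_class


def _expand_structure(
    spec: CodonModelSpec, tree: Phylogeny
) -> tuple[np.ndarray, np.ndarray]:
    """(class_weights, class_branch_omegas) from an omega structure."""
    n_nodes = tree.n_nodes
    struct = spec.omega_structure
    if isinstance(struct, SiteMixtureSpec):
        w, om = struct.categories()
        return w, np.repeat(om[:, None], n_nodes, axis=1)
    if isinstance(struct, Mapping):
        row = np.empty(n_nodes)
        for b in tree.branch_ids():
            if b not in struct:
                raise ValueError(f"no omega for branch {b} ({tree.labels[b]})")
            row[b] = struct[b]
        row[tree.root] = 1.0  # unused
        return np.array([1.0]), row[None, :]
    return np.array([1.0]), np.full((1, n_nodes), float(struct))


def log_likelihood(
    alignment: CodonAlignment, tree: Phylogeny, spec: CodonModelSpec
) -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree.

    Gapped/ambiguous tip states sum over all compatible codons.  Site
    mixtures average class likelihoods site by site.
    """
    missing = set(alignment.taxa) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    patterns, counts = _compress(alignment.codes)
    w, cbo = _expand_structure(spec, tree)
    site, _ = _site_logliks(
        patterns, alignment.taxa, tree, spec.kappa, spec.freqs, w, cbo,
        tree.lengths,
    )
    return float(site @ counts)


# ------------------------------------------------------------ dN/dS fluxes

def _flux_fractions(kappa: float, freqs: np.ndarray, omega: float) -> tuple[float, float]:
    """(nonsynonymous, synonymous) fractions of total substitution flux."""
    Q = _rate_matrix(kappa, freqs, omega)
    flux = freqs[_PAIR_I] * Q[_PAIR_I, _PAIR_J]
    total = flux.sum()
    rho_n = flux[~_PAIR_SYN].sum() / total
    return rho_n, 1.0 - rho_n


def branch_expected_subs(
    spec: CodonModelSpec, omega: float, t: float
) -> tuple[float, float]:
    """Expected (dN, dS) per non/synonymous site along a branch.

    Substitution flux at the branch's omega is split into nonsynonymous
    and synonymous parts and divided by the corresponding site proportions
    under the mutational null (same kappa and frequencies, omega = 1), so
    omega = 1 gives dN = dS = t exactly.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    rho_n, rho_s = _flux_fractions(spec.kappa, spec.freqs, omega)
    p_n, p_s = _flux_fractions(spec.kappa, spec.freqs, 1.0)
    dN = t * rho_n / p_n
    dS = t * rho_s / p_s if p_s > 0 else 0.0
    return dN, dS


# ------------------------------------------------------------------ fitting

@dataclass
class _Param:
    name: str
    init: float
    lo: float
    hi: float
    log: bool = False

    def to_x(self, v: float) -> float:
        return np.log(v) if self.log else v

    def from_x(self, x: float) -> float:
        return float(np.exp(x)) if self.log else float(x)

    def bounds(self) -> tuple[float, float]:
        return (
            (np.log(self.lo), np.log(self.hi)) if self.log else (self.lo, self.hi)
        )


_OMEGA_LO, _OMEGA_HI = 1e-6, 50.0
_KAPPA_LO, _KAPPA_HI = 0.1, 20.0
_BL_LO, _BL_HI = 1e-7, 20.0
_BETA_LO, _BETA_HI = 5e-3, 99.0
_PROP_LO, _PROP_HI = 1e-6, 1 - 1e-6


def _model_params(model_id: str, tree: Phylogeny) -> list[_Param]:
    if model_id == "M0":
        return [_Param("omega", 0.4, _OMEGA_LO, _OMEGA_HI, log=True)]
    if model_id == "M1a":
        return [
            _Param("p0", 0.7, _PROP_LO, _PROP_HI),
            _Param("omega0", 0.2, _PROP_LO, _PROP_HI),
        ]
    if model_id == "M2a":
        return [
            _Param("s0", 0.6, _PROP_LO, _PROP_HI),
            _Param("s1", 0.7, _PROP_LO, _PROP_HI),
            _Param("omega0", 0.2, _PROP_LO, _PROP_HI),
            _Param("omega2", 2.5, 1.0, _OMEGA_HI, log=True),
        ]
    if model_id == "M7":
        return [
            _Param("p", 0.5, _BETA_LO, _BETA_HI, log=True),
            _Param("q", 1.0, _BETA_LO, _BETA_HI, log=True),
        ]
    if model_id == "M8":
        return [
            _Param("p0", 0.85, _PROP_LO, _PROP_HI),
            _Param("p", 0.5, _BETA_LO, _BETA_HI, log=True),
            _Param("q", 1.0, _BETA_LO, _BETA_HI, log=True),
            _Param("omega_s", 2.0, 1.0, _OMEGA_HI, log=True),
        ]
    if model_id == "two-ratio":
        return [
            _Param("omega_fg", 0.8, _OMEGA_LO, _OMEGA_HI, log=True),
            _Param("omega_bg", 0.4, _OMEGA_LO, _OMEGA_HI, log=True),
        ]
    if model_id == "free-ratio":
        return [
            _Param(f"omega_b{b}", 0.4, _OMEGA_LO, _OMEGA_HI, log=True)
            for b in tree.branch_ids()
        ]
    raise ValueError(f"unknown model_id {model_id!r}")


def _structure_from_params(
    model_id: str,
    p: Mapping[str, float],
    tree: Phylogeny,
    foreground: set[int] | None,
    ncat: int,
) -> float | dict[int, float] | SiteMixtureSpec:
    if model_id == "M0":
        return p["omega"]
    if model_id == "M1a":
        return SiteMixtureSpec(
            "M1a", classes=[(p["p0"], p["omega0"]), (1 - p["p0"], 1.0)]
        )
    if model_id == "M2a":
        p0 = p["s0"]
        p1 = (1 - p["s0"]) * p["s1"]
        p2 = 1 - p0 - p1
        return SiteMixtureSpec(
            "M2a",
            classes=[(p0, p["omega0"]), (p1, 1.0), (p2, p["omega2"])],
        )
    if model_id == "M7":
        return SiteMixtureSpec(
            "M7", beta=(p["p"], p["q"]), beta_weight=1.0, ncat=ncat
        )
    if model_id == "M8":
        return SiteMixtureSpec(
            "M8",
            classes=[(1 - p["p0"], p["omega_s"])],
            beta=(p["p"], p["q"]),
            beta_weight=p["p0"],
            ncat=ncat,
        )
    if model_id == "two-ratio":
        if not foreground:
            raise ValueError("two-ratio model requires a foreground branch set")
        return {
            b: (p["omega_fg"] if b in foreground else p["omega_bg"])
            for b in tree.branch_ids()
        }
    if model_id == "free-ratio":
        return {b: p[f"omega_b{b}"] for b in tree.branch_ids()}
    raise ValueError(model_id)


def _mixture_params(model_id: str, p: Mapping[str, float]) -> dict[str, float]:
    """Reported (natural-parameterisation) estimates per model."""
    out = dict(p)
    if model_id == "M1a":
        out["p1"] = 1 - p["p0"]
    if model_id == "M2a":
        out["p0"] = p["s0"]
        out["p1"] = (1 - p["s0"]) * p["s1"]
        out["p2"] = 1 - out["p0"] - out["p1"]
        out.pop("s0"), out.pop("s1")
    if model_id == "M8":
        out["p1"] = 1 - p["p0"]
    return out


# deterministic alternative starting points per model; mixture surfaces
# (especially M2a/M8) are multimodal, so restarts cover qualitatively
# different regimes (mostly-neutral, strong-selection, nearly-one-class)
_START_GRID: dict[str, list[dict[str, float]]] = {
    "M0": [{"omega": 1.5}, {"omega": 0.05}],
    "M1a": [{"p0": 0.4, "omega0": 0.5}, {"p0": 0.9, "omega0": 0.05}],
    "M2a": [
        {"s0": 0.5, "s1": 0.85, "omega0": 0.1, "omega2": 4.0},
        {"s0": 0.35, "s1": 0.6, "omega0": 0.4, "omega2": 1.5},
        {"s0": 0.8, "s1": 0.5, "omega0": 0.05, "omega2": 8.0},
    ],
    "M7": [{"p": 0.1, "q": 0.1}, {"p": 2.0, "q": 2.0}],
    "M8": [
        {"p0": 0.6, "p": 0.1, "q": 0.2, "omega_s": 3.0},
        {"p0": 0.95, "p": 1.0, "q": 2.0, "omega_s": 1.5},
    ],
    "two-ratio": [
        {"omega_fg": 2.0, "omega_bg": 0.2},
        {"omega_fg": 0.2, "omega_bg": 1.0},
    ],
}


def fit(
    alignment: CodonAlignment,
    tree: Phylogeny,
    model_id: str,
    fixed: Mapping[str, float] | None = None,
    *,
    foreground: set[int] | None = None,
    freq_model: str = "F3X4",
    ncat: int = 10,
    optimize_branch_lengths: bool = True,
    cleandata: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of a codon model.

    ``fixed`` pins named parameters (e.g. ``{"omega_fg": 1.0}`` for the
    relaxation null, or ``{"kappa": 2.0}``); pinned parameters are held at
    the given value and excluded from the free-parameter count.  Branch
    lengths start from the input tree and are optimised jointly unless
    ``optimize_branch_lengths=False``.  ``n_starts`` deterministic restarts
    (seeded) guard against local optima; the best fit is returned.
    """
    fixed = dict(fixed or {})
    if cleandata:
        alignment = alignment.clean_columns()
    if alignment.n_codons == 0:
        raise ValueError("no codon columns left after cleaning")
    patterns, counts = _compress(alignment.codes)
    freqs = codon_frequencies(alignment, freq_model)
    params = [_Param("kappa", 2.0, _KAPPA_LO, _KAPPA_HI, log=True)]
    params += _model_params(model_id, tree)
    if optimize_branch_lengths:
        init_bl = np.where(tree.lengths > 1e-6, tree.lengths, 0.05)
        params += [
            _Param(f"t_b{b}", float(init_bl[b]), _BL_LO, _BL_HI, log=True)
            for b in tree.branch_ids()
        ]
    free = [pr for pr in params if pr.name not in fixed]

    def unpack(x: np.ndarray) -> dict[str, float]:
        vals = dict(fixed)
        for pr, xi in zip(free, x):
            vals[pr.name] = pr.from_x(xi)
        for pr in params:
            vals.setdefault(pr.name, pr.init)
        return vals

    def branch_lengths_of(vals: Mapping[str, float]) -> np.ndarray:
        if optimize_branch_lengths:
            bl = np.zeros(tree.n_nodes)
            for b in tree.branch_ids():
                bl[b] = vals[f"t_b{b}"]
            return bl
        return tree.lengths

    def neg_lnl(x: np.ndarray) -> float:
        vals = unpack(x)
        struct = _structure_from_params(model_id, vals, tree, foreground, ncat)
        spec = CodonModelSpec(vals["kappa"], freqs, struct, freq_model)
        w, cbo = _expand_structure(spec, tree)
        site, _ = _site_logliks(
            patterns, alignment.taxa, tree, spec.kappa, freqs, w, cbo,
            branch_lengths_of(vals),
        )
        val = site @ counts
        return -val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    x0 = np.array([pr.to_x(pr.init) for pr in free])
    bounds = [pr.bounds() for pr in free]
    start_grid = _START_GRID.get(model_id, [])
    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            start = x0
        elif s - 1 < len(start_grid):
            overrides = start_grid[s - 1]
            start = np.array([
                pr.to_x(overrides.get(pr.name, pr.init)) for pr in free
            ])
        else:
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            jitter = rng.uniform(-1.0, 1.0, size=len(free))
            start = np.clip(x0 + jitter, lo, hi)
        res = optimize.minimize(
            neg_lnl, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    vals = unpack(best.x)
    struct = _structure_from_params(model_id, vals, tree, foreground, ncat)
    spec = CodonModelSpec(vals["kappa"], freqs, struct, freq_model)
    bl = branch_lengths_of(vals)
    table = _branch_table(spec, tree, bl, struct)
    reported = {
        k: v for k, v in _mixture_params(model_id, vals).items()
        if not k.startswith("t_b")
    }
    return FitResult(
        model_id=model_id,
        lnL=float(-best.fun),
        spec=spec,
        params=reported,
        branch_lengths=bl,
        branch_table=table,
        n_params=len(free),
        converged=bool(best.success),
        tree=tree,
        foreground=foreground,
    )


def _branch_table(
    spec: CodonModelSpec,
    tree: Phylogeny,
    branch_lengths: np.ndarray,
    struct,
) -> pd.DataFrame:
    """Per-branch (t, omega, dN, dS); mixture models use the mean omega."""
    rows = []
    for b in tree.branch_ids():
        if isinstance(struct, SiteMixtureSpec):
            om = struct.mean_omega()
        elif isinstance(struct, Mapping):
            om = float(struct[b])
        else:
            om = float(struct)
        t = float(branch_lengths[b])
        dN, dS = branch_expected_subs(spec, om, t)
        rows.append(
            {"branch": tree.labels[b], "node": b, "t": t, "omega": om,
             "dN": dN, "dS": dS}
        )
    return pd.DataFrame(rows)


def choose_frequency_model(
    alignment: CodonAlignment,
    tree: Phylogeny,
    candidates: Sequence[str] = ("equal", "F1X4", "F3X4", "F61"),
    **fit_kwargs,
) -> str:
    """Pick the codon-frequency model by AIC of single-ratio (M0) fits.

    Frequency parameter counts: equal 0, F1X4 3, F3X4 9, F61 60 (empirical
    counts, charged to the model as in common practice).
    """
    extra = {"equal": 0, "F1X4": 3, "F3X4": 9, "F61": 60}
    best_model, best_aic = None, np.inf
    for cand in candidates:
        r = fit(alignment, tree, "M0", freq_model=cand, **fit_kwargs)
        aic = 2 * (r.n_params + extra[cand]) - 2 * r.lnL
        if aic < best_aic:
            best_model, best_aic = cand, aic
    return best_model
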