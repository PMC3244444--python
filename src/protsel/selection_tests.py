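"""Model comparisons and site classification.

The inference logic of the analysis: likelihood-ratio tests between
nested codon models, the clade decision rule separating positive
selection from relaxation of constraint, the M1a/M2a and M7/M8 site-model
test pairs, and Bayes Empirical Bayes (BEB) classification of sites into
three selective classes (1: omega<1 purifying, 2: omega~1 neutral,
3: omega>1 positive selection or relaxation).

The clade rule: the foreground clade is under POSITIVE selection when it
evolves at a rate significantly different from the background (one-ratio
vs two-ratio), that rate is significantly different from 1 (fixed-omega=1
two-ratio vs free two-ratio), and the estimate exceeds 1.  It is a
RELAXATION candidate when the first test is significant but the second is
not — the clade's omega differs from the background yet is statistically
indistinguishable from neutrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codon_model import (
    FitResult, SiteMixtureSpec, _compress, _site_logliks, fit,
)
from .seqio import CodonAlignment
from .trees import Phylogeny

__all__ = [
    "LRTResult", "CladeDecision", "SitePosterior", "SiteClassSummary",
    "lrt", "fit_clade_suite", "classify_clade", "decide_clade_label",
    "fit_site_suite", "SiteSuiteResult", "beb_classify",
    "summarize_site_classes",
]

# nested (null, alternative) model pairs accepted by lrt()
_NESTED = {
    ("M0", "two-ratio"), ("two-ratio", "two-ratio"), ("M0", "free-ratio"),
    ("M1a", "M2a"), ("M7", "M8"), ("M0", "M1a"), ("M0", "M2a"),
    ("M0", "M8"),
}
_NEG_2DL_TOL = 0.1


@dataclass
class LRTResult:
    """A likelihood-ratio test between two nested fits."""

    model_null: str
    model_alt: str
    lnL_null: float
    lnL_alt: float
    two_delta_l: float
    df: int
    p_value: float
    verdict: str  # "ns" | "*" | "**"

    @property
    def significant(self) -> bool:
        return self.verdict != "ns"


def lrt(fit_null: FitResult, fit_alt: FitResult) -> LRTResult:
    """2*(lnL_alt - lnL_null) against chi-square(df = extra parameters).

    Small negative statistics (optimiser noise on a boundary) are clamped
    to zero; verdicts are ``**`` at 0.01, ``*`` at 0.05, else ``ns``.
    """
    if (fit_null.model_id, fit_alt.model_id) not in _NESTED:
        raise ValueError(
            f"models {fit_null.model_id!r} and {fit_alt.model_id!r} are not "
            "a supported nested pair"
        )
    df = fit_alt.n_params - fit_null.n_params
    if df < 1:
        raise ValueError(
            "alternative must have more free parameters than the null "
            f"({fit_alt.n_params} vs {fit_null.n_params})"
        )
    stat = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if stat < 0:
        if stat < -_NEG_2DL_TOL:
            warnings.warn(
                f"2*delta-lnL = {stat:.4f} < 0 beyond tolerance; "
                "check convergence", stacklevel=2,
            )
        stat = 0.0
    p = float(stats.chi2.sf(stat, df))
    verdict = "**" if p < 0.01 else ("*" if p < 0.05 else "ns")
    return LRTResult(
        model_null=fit_null.model_id, model_alt=fit_alt.model_id,
        lnL_null=fit_null.lnL, lnL_alt=fit_alt.lnL,
        two_delta_l=stat, df=df, p_value=p, verdict=verdict,
    )


# ----------------------------------------------------------- clade models

@dataclass
class CladeDecision:
    """Outcome of the three-model clade analysis."""

    foreground_omega: float
    lrt_m1_vs_m3: LRTResult
    lrt_m2_vs_m3: LRTResult
    label: str  # "Positive" | "Relaxation" | "None"


def fit_clade_suite(
    alignment: CodonAlignment,
    tree: Phylogeny,
    foreground: list[str] | set[int],
    *,
    include_stem: bool = True,
    **fit_kwargs,
) -> tuple[FitResult, FitResult, FitResult]:
    """Fit the one-ratio, fixed-foreground and free two-ratio models.

    ``foreground`` is either a list of tip labels (must span a connected
    clade; ``include_stem`` adds the stem branch) or an explicit set of
    branch ids.  Returns (m1, m2, m3): m1 single omega everywhere; m2
    background free, foreground pinned at omega=1 (the relaxation null);
    m3 both free.
    """
    if not isinstance(foreground, set) or not all(
        isinstance(b, (int, np.integer)) for b in foreground
    ):
        foreground = tree.clade_branches(list(foreground), include_stem)
    m1 = fit(alignment, tree, "M0", **fit_kwargs)
    m2 = fit(
        alignment, tree, "two-ratio", fixed={"omega_fg": 1.0},
        foreground=foreground, **fit_kwargs,
    )
    m3 = fit(alignment, tree, "two-ratio", foreground=foreground, **fit_kwargs)
    return m1, m2, m3


def decide_clade_label(
    foreground_omega: float,
    m1_vs_m3_significant: bool,
    m2_vs_m3_significant: bool,
) -> str:
    """The pure decision rule over (omega_fg, significance pattern).

    Positive: both tests significant and omega_fg > 1.  Relaxation: rate
    differs from background (test 1) but not from 1 (test 2 ns).  The
    table is exhaustive and mutually exclusive; anything else is "None".
    """
    if m1_vs_m3_significant and m2_vs_m3_significant and foreground_omega > 1:
        return "Positive"
    if m1_vs_m3_significant and not m2_vs_m3_significant:
        return "Relaxation"
    return "None"


def classify_clade(
    m1: FitResult, m2: FitResult, m3: FitResult, alpha: float = 0.05
) -> CladeDecision:
    """Apply the clade decision rule to the fitted model triple."""
    t1 = lrt(m1, m3)
    t2 = lrt(m2, m3)
    omega_fg = m3.params["omega_fg"]
    label = decide_clade_label(
        omega_fg, t1.p_value < alpha, t2.p_value < alpha
    )
    return CladeDecision(
        foreground_omega=omega_fg, lrt_m1_vs_m3=t1, lrt_m2_vs_m3=t2,
        label=label,
    )


# ------------------------------------------------------------ site models

@dataclass
class SiteSuiteResult:
    """Fits and tests of the site-model suite."""

    fits: dict[str, FitResult]
    lrt_m1a_m2a: LRTResult
    lrt_m7_m8: LRTResult
    designation_m1a_m2a: str   # "M2a (selection)" or "M1a (neutral)"
    designation_m7_m8: str     # "M8 (beta and omega)" or "M7 (beta)"


def fit_site_suite(
    alignment: CodonAlignment, tree: Phylogeny, **fit_kwargs
) -> SiteSuiteResult:
    """Fit M0/M1a/M2a/M7/M8 and run the two positive-selection LRTs."""
    fits = {
        m: fit(alignment, tree, m, **fit_kwargs)
        for m in ("M0", "M1a", "M2a", "M7", "M8")
    }
    t12 = lrt(fits["M1a"], fits["M2a"])
    t78 = lrt(fits["M7"], fits["M8"])
    return SiteSuiteResult(
        fits=fits,
        lrt_m1a_m2a=t12,
        lrt_m7_m8=t78,
        designation_m1a_m2a=(
            "M2a (selection)" if t12.significant else "M1a (neutral)"
        ),
        designation_m7_m8=(
            "M8 (beta and omega)" if t78.significant else "M7 (beta)"
        ),
    )


# ------------------------------------------------------------------- BEB

@dataclass
class SitePosterior:
    """Per-site posterior classification under a site-mixture model."""

    model_id: str
    class_probs: np.ndarray        # (L, 3) selective-class posteriors
    mean_omega: np.ndarray         # (L,) posterior mean omega
    se_omega: np.ndarray           # (L,) posterior s.d. of omega
    assigned_class: np.ndarray     # (L,) in {1, 2, 3}
    ps_allowed: bool               # class-3 flags permitted (M2a/M8 only)
    pp95: list[int] = field(default_factory=list)  # 0-based sites, PP>0.95
    pp99: list[int] = field(default_factory=list)
    method: str = "BEB"

    @property
    def n_sites(self) -> int:
        return self.class_probs.shape[0]


_SELECTED_CAPABLE = {"M2a", "M8"}
# a mixture component is "neutral-like" (class 2) when omega is this close to 1
_CLASS2_BAND = 0.05


def _component_class(omega: float, selected: bool) -> int:
    if selected:
        return 3
    if omega > 1 + _CLASS2_BAND:
        return 3
    if omega >= 1 - _CLASS2_BAND:
        return 2
    return 1


def _grid_points(model_id: str, fit_result: FitResult, g: int):
    """BEB grid: list of (weights, omegas, selected_mask) per grid point.

    Grids follow the published BEB construction: mixture proportions and
    the free omegas get ``g`` midpoint values each (uniform prior); shape
    parameters of the M8 beta are held at their MLEs.  M7 (no free
    selection parameter of interest) uses the 1-point MLE grid, which
    makes BEB coincide with NEB.
    """
    mid = (2 * np.arange(g) + 1) / (2 * g)       # g midpoints in (0,1)
    omega2_grid = 1.0 + 10.0 * mid                # (1, 11)
    p = fit_result.params
    points = []
    if model_id == "M1a":
        for p0 in mid:
            for w0 in mid:
                points.append((np.array([p0, 1 - p0]), np.array([w0, 1.0]),
                               np.array([False, False])))
    elif model_id == "M2a":
        for p0 in mid:
            for p1 in mid:
                if p0 + p1 >= 1:
                    continue
                for w0 in mid:
                    for w2 in omega2_grid:
                        points.append((
                            np.array([p0, p1, 1 - p0 - p1]),
                            np.array([w0, 1.0, w2]),
                            np.array([False, False, True]),
                        ))
    elif model_id == "M8":
        mix = SiteMixtureSpec(
            "M7", beta=(p["p"], p["q"]), beta_weight=1.0,
            ncat=fit_result.spec.omega_structure.ncat,
        )
        _, beta_omegas = mix.categories()
        k = len(beta_omegas)
        for p0 in mid:
            for ws in omega2_grid:
                points.append((
                    np.concatenate([np.full(k, p0 / k), [1 - p0]]),
                    np.concatenate([beta_omegas, [ws]]),
                    np.concatenate([np.zeros(k, bool), [True]]),
                ))
    elif model_id == "M7":
        w, om = fit_result.spec.omega_structure.categories()
        points.append((w, om, np.zeros(len(om), bool)))
    else:
        raise ValueError(f"BEB not defined for model {model_id!r}")
    return points


def _mle_point(fit_result: FitResult):
    struct = fit_result.spec.omega_structure
    w, om = struct.categories()
    selected = np.zeros(len(om), bool)
    if fit_result.model_id == "M2a":
        selected[-1] = True
    elif fit_result.model_id == "M8":
        selected[-1] = True  # categories() puts the extra class last
    return [(w, om, selected)]


def beb_classify(
    alignment: CodonAlignment,
    tree: Phylogeny,
    fit_result: FitResult,
    *,
    grid_size: int = 10,
    neb: bool = False,
    cleandata: bool = True,
) -> SitePosterior:
    """Bayes Empirical Bayes site classification under a site-mixture fit.

    Empirical-Bayes posteriors over the mixture classes are averaged over
    a discrete grid prior on the mixture parameters, each grid point
    weighted by its integrated likelihood; this absorbs the estimation
    error a plug-in (NEB) analysis ignores.  ``neb=True`` (or a 1-point
    grid) collapses to NEB exactly.  Class-3 "positively selected" flags
    (PP > 0.95 / 0.99) are only permitted under M2a and M8.
    """
    model_id = fit_result.model_id
    if model_id not in ("M1a", "M2a", "M7", "M8"):
        raise ValueError(f"site classification needs a mixture fit, got {model_id}")
    if cleandata:
        alignment = alignment.clean_columns()
    codes = alignment.codes
    patterns, _counts = _compress(codes)
    # pattern membership per original site
    _, inverse = np.unique(codes.T, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)

    points = (
        _mle_point(fit_result) if (neb or grid_size == 1)
        else _grid_points(model_id, fit_result, grid_size)
    )
    # site log-likelihood per distinct omega, at the fitted branch
    # lengths/kappa/frequencies
    freqs = fit_result.spec.freqs
    kappa = fit_result.spec.kappa
    all_omegas = sorted({float(om) for _, oms, _ in points for om in oms})
    omega_index = {om: i for i, om in enumerate(all_omegas)}
    F = np.empty((len(all_omegas), patterns.shape[1]))
    for om, i in omega_index.items():
        site, _ = _site_logliks(
            patterns, alignment.taxa, tree, kappa, freqs,
            np.array([1.0]), np.full((1, tree.n_nodes), om),
            fit_result.branch_lengths,
        )
        F[i] = site

    n_pat = patterns.shape[1]
    post3 = np.zeros((3, n_pat))
    m1 = np.zeros(n_pat)   # E[omega | site]
    m2 = np.zeros(n_pat)   # E[omega^2 | site]
    log_integrated = np.empty(len(points))
    per_point = []
    for gi, (w, oms, sel) in enumerate(points):
        idx = np.array([omega_index[float(om)] for om in oms])
        logm = F[idx] + np.log(w)[:, None]
        mmax = logm.max(axis=0)
        mix = np.exp(logm - mmax)
        denom = mix.sum(axis=0)
        resp = mix / denom                       # (K, n_pat) class posteriors
        log_integrated[gi] = float((mmax + np.log(denom)) @ counts)
        per_point.append((resp, oms, sel))
    log_w = log_integrated - log_integrated.max()
    gw = np.exp(log_w)
    gw /= gw.sum()
    for gi, (resp, oms, sel) in enumerate(per_point):
        cls = np.array([
            _component_class(float(om), bool(s)) for om, s in zip(oms, sel)
        ])
        for c in (1, 2, 3):
            mask = cls == c
            if mask.any():
                post3[c - 1] += gw[gi] * resp[mask].sum(axis=0)
        m1 += gw[gi] * (oms @ resp)
        m2 += gw[gi] * ((oms**2) @ resp)

    # expand patterns back to sites
    class_probs = post3.T[inverse]
    mean_omega = m1[inverse]
    var = np.maximum(m2[inverse] - mean_omega**2, 0.0)
    se_omega = np.sqrt(var)
    assigned = class_probs.argmax(axis=1) + 1
    ps_allowed = model_id in _SELECTED_CAPABLE
    pp95 = (
        [int(i) for i in np.where(class_probs[:, 2] > 0.95)[0]]
        if ps_allowed else []
    )
    pp99 = (
        [int(i) for i in np.where(class_probs[:, 2] > 0.99)[0]]
        if ps_allowed else []
    )
    return SitePosterior(
        model_id=model_id,
        class_probs=class_probs,
        mean_omega=mean_omega,
        se_omega=se_omega,
        assigned_class=assigned,
        ps_allowed=ps_allowed,
        pp95=pp95,
        pp99=pp99,
        method="NEB" if (neb or grid_size == 1) else "BEB",
    )


# --------------------------------------------------------------- summaries

@dataclass
class SiteClassSummary:
    """Percent of sites per selective class, overall and per region type."""

    overall: dict[int, float]
    per_region: dict[str, dict[int, float]]
    positively_selected: list[str]        # residue labels, e.g. "33C*"
    notes: list[str] = field(default_factory=list)


def _percentages(classes: np.ndarray) -> dict[int, float]:
    n = len(classes)
    return {
        c: round(100.0 * float((classes == c).sum()) / n, 2) for c in (1, 2, 3)
    }


def site_label(
    site: int, alignment: CodonAlignment, reference: str
) -> str:
    """Residue label like ``33C``: 1-based position + reference residue."""
    aa = alignment.translate(reference)
    return f"{site + 1}{aa[site]}"


def summarize_site_classes(
    posterior: SitePosterior,
    regions=None,
    *,
    alignment: CodonAlignment | None = None,
    reference: str | None = None,
) -> SiteClassSummary:
    """Percent of sites in classes 1/2/3 overall and within region types.

    ``regions`` is a domain annotation (object with ``.regions`` of
    (type, (start, stop), source) entries) on the same residue coordinate
    system as the posterior.  Positively selected sites are labelled in
    reference numbering when an alignment and reference taxon are given;
    under M1a/M7 the list reads "not allowed".
    """
    L = posterior.n_sites
    overall = _percentages(posterior.assigned_class)
    per_region: dict[str, dict[int, float]] = {}
    notes: list[str] = []
    if regions is not None:
        by_type: dict[str, set[int]] = {}
        for rtype, (start, stop), _source in regions.regions:
            if stop > L or start < 0:
                raise IndexError(
                    f"region [{start},{stop}) outside alignment of {L} sites"
                )
            by_type.setdefault(rtype, set()).update(range(start, stop))
        for rtype, sites in sorted(by_type.items()):
            if not sites:
                notes.append(f"region type {rtype!r} covers no sites; omitted")
                continue
            idx = np.array(sorted(sites))
            per_region[rtype] = _percentages(posterior.assigned_class[idx])
    ps: list[str] = []
    if not posterior.ps_allowed:
        ps = ["not allowed"]
    else:
        for site in sorted(set(posterior.pp95)):
            star = "**" if site in posterior.pp99 else "*"
            if alignment is not None and reference is not None:
                ps.append(site_label(site, alignment, reference) + star)
            else:
                ps.append(f"{site + 1}{star}")
    return SiteClassSummary(
        overall=overall, per_region=per_region,
        positively_selected=ps, notes=notes,
    )


def summary_from_assignments(
    assigned: np.ndarray, regions=None
) -> SiteClassSummary:
    """Summary straight from a hand-assigned class vector (1/2/3)."""
    fake = SitePosterior(
        model_id="M2a",
        class_probs=np.eye(3)[np.asarray(assigned) - 1],
        mean_omega=np.zeros(len(assigned)),
        se_omega=np.zeros(len(assigned)),
        assigned_class=np.asarray(assigned),
        ps_allowed=True,
    )
    return summarize_site_classes(fake, regions)
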