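"""Synthetic codon alignments and trait tables.

Generative twins of the likelihood machinery: codon alignments evolved
under single-ratio, branch-partition (clade) or site-mixture omega
regimes, and bivariate species traits with phylogenetically structured
covariance exp(-alpha * d).  All randomness flows from one integer seed;
every dataset carries a :class:`SimulationTruth` that reproduces it.

The bundled trees are SYNTHETIC stand-ins shaped like the study system
(a Cricetidae radiation with murid background and outgroup): topology and
branch lengths are plausible for protamine-scale divergence but are not
literature reconstructions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_model import (
    CodonModelSpec, SiteMixtureSpec, _EigGenerator, _expand_structure,
    _rate_matrix, N_STATES,
)
from .seqio import CODONS, CODON_AA, CodonAlignment, write_fasta
from .trees import Phylogeny

__all__ = [
    "SimulationTruth", "simulate_codon_alignment", "simulate_traits",
    "make_fixture_set", "study_tree", "clade_tree", "trait_tree",
    "site_tree", "CRICETIDAE_TAXA", "SITE_TREE_SCALE",
]

# 16 study species + outgroup; subfamily structure mirrors the study group
# (10 Arvicolinae, 5 Cricetinae, 1 Sigmodontinae).  Synthetic lengths.
_STUDY_NEWICK = (
    "((((((Microtus_arvalis:0.020,Microtus_cabrerae:0.020):0.015,"
    "(Microtus_agrestis:0.025,Microtus_gerbei:0.020):0.010):0.010,"
    "(Pitymys_duodecimcostatus:0.020,Pitymys_lusitanicus:0.020):0.020):0.015,"
    "((Arvicola_sapidus:0.020,Arvicola_terrestris:0.020):0.030,"
    "(Chionomys_nivalis:0.040,Clethrionomys_glareolus:0.050):0.010):0.010):0.040,"
    "(((Cricetulus_griseus:0.060,Mesocricetus_auratus:0.060):0.020,"
    "(Phodopus_roborovskii:0.040,(Phodopus_sungorus:0.020,"
    "Phodopus_campbelli:0.020):0.020):0.030):0.030,"
    "Sigmodon_hispidus:0.120):0.010):0.050,Mus_musculus:0.150);"
)

# clade-analysis tree: an 8-taxon Cricetidae foreground, 7 murid background
# species, rabbit outgroup (16 taxa total).
_CLADE_NEWICK = (
    "(((((Microtus_arvalis:0.030,Microtus_agrestis:0.030):0.030,"
    "(Arvicola_sapidus:0.040,(Chionomys_nivalis:0.040,"
    "Clethrionomys_glareolus:0.040):0.010):0.020):0.040,"
    "((Cricetulus_griseus:0.060,Mesocricetus_auratus:0.050):0.020,"
    "Phodopus_sungorus:0.070):0.030):0.060,"
    "(((Mus_musculus:0.020,Mus_spretus:0.020):0.060,"
    "Apodemus_sylvaticus:0.080):0.030,"
    "((Rattus_norvegicus:0.020,Rattus_rattus:0.020):0.080,"
    "(Meriones_unguiculatus:0.100,Micromys_minutus:0.090):0.020):0.020):0.050"
    "):0.100,Oryctolagus_cuniculus:0.350);"
)

#: foreground (Cricetidae) tips of :func:`clade_tree`
CRICETIDAE_TAXA = [
    "Microtus_arvalis", "Microtus_agrestis", "Arvicola_sapidus",
    "Chionomys_nivalis", "Clethrionomys_glareolus", "Cricetulus_griseus",
    "Mesocricetus_auratus", "Phodopus_sungorus",
]

# 14-taxon trait tree: the study species minus the Prm2 pseudogene carrier
# (Cricetulus griseus) and the database-only Sigmodon hispidus.
_TRAIT_NEWICK = (
    "((((Microtus_arvalis:0.020,Microtus_cabrerae:0.020):0.015,"
    "(Microtus_agrestis:0.025,Microtus_gerbei:0.020):0.010):0.010,"
    "((Pitymys_duodecimcostatus:0.020,Pitymys_lusitanicus:0.020):0.020,"
    "((Arvicola_sapidus:0.020,Arvicola_terrestris:0.020):0.030,"
    "(Chionomys_nivalis:0.040,Clethrionomys_glareolus:0.050):0.010):0.005"
    "):0.010):0.040,"
    "(Mesocricetus_auratus:0.080,(Phodopus_roborovskii:0.040,"
    "(Phodopus_sungorus:0.020,Phodopus_campbelli:0.020):0.020):0.040):0.030);"
)


def study_tree() -> Phylogeny:
    """17-taxon rooted tree (16 study species + Mus outgroup). Synthetic."""
    return Phylogeny.from_newick(_STUDY_NEWICK)


def clade_tree() -> Phylogeny:
    """16-taxon clade-analysis tree: Cricetidae foreground, murid background,
    rabbit outgroup. Synthetic."""
    return Phylogeny.from_newick(_CLADE_NEWICK)


def trait_tree() -> Phylogeny:
    """14-taxon tree for the comparative (pGLS) analyses. Synthetic."""
    return Phylogeny.from_newick(_TRAIT_NEWICK)


#: branch-length scale for site-model simulation worlds.  The base study
#: tree is conservative (~1 substitution/codon over the whole tree);
#: fast-evolving protamine codon trees at this taxon breadth carry several
#: substitutions per site, which is what site-level inference needs.
SITE_TREE_SCALE = 4.0


def site_tree() -> Phylogeny:
    """Study tree with branch lengths scaled for site-model simulations."""
    t = study_tree()
    return t.with_lengths(t.lengths * SITE_TREE_SCALE)


@dataclass
class SimulationTruth:
    """Everything needed to regenerate and grade a simulated dataset."""

    model_id: str
    kappa: float
    freq_model: str
    omega_structure: dict | float
    site_classes: list[int] | None        # true class per site (site models)
    site_omegas: list[float] | None       # true omega per site
    newick: str
    seed: int
    n_codons: int
    realized_counts: dict | None = None   # per-branch {syn, nonsyn} (gillespie)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _sample_states(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    """Vectorised categorical draw: child state per site given parent row."""
    cdf = P.cumsum(axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(parents.shape[0])
    return (cdf[parents] < u[:, None]).sum(axis=1).astype(np.int16)


def _gillespie_branch(
    Q: np.ndarray, t: float, states: np.ndarray, rng
) -> tuple[np.ndarray, int, int]:
    """Event-by-event simulation of one branch; counts syn/nonsyn events."""
    out = states.copy()
    n_syn = n_non = 0
    rates = -np.diag(Q)
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump / jump.sum(axis=1, keepdims=True)
    jump_cdf = jump.cumsum(axis=1)
    for s in range(out.shape[0]):
        clock, state = 0.0, int(out[s])
        while True:
            clock += rng.exponential(1.0 / rates[state])
            if clock > t:
                break
            nxt = int(np.searchsorted(jump_cdf[state], rng.random()))
            if CODON_AA[state] == CODON_AA[nxt]:
                n_syn += 1
            else:
                n_non += 1
            state = nxt
        out[s] = state
    return out, n_syn, n_non


def simulate_codon_alignment(
    tree: Phylogeny,
    spec: CodonModelSpec,
    n_codons: int,
    seed: int,
    gene_label: str = "sim",
    gillespie: bool = False,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment along ``tree`` under ``spec``.

    Root codons are drawn from the equilibrium frequencies; each site is
    independently assigned a mixture class (site models); child states are
    drawn from exact transition probabilities per branch — or event by
    event when ``gillespie=True``, which additionally records realized
    synonymous/nonsynonymous substitution counts per branch.  The state
    space excludes stop codons, so none are ever emitted.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    weights, class_branch_omegas = _expand_structure(spec, tree)
    n_class = weights.shape[0]
    site_class = (
        rng.choice(n_class, size=n_codons, p=weights) if n_class > 1
        else np.zeros(n_codons, dtype=int)
    )
    root_states = rng.choice(N_STATES, size=n_codons, p=spec.freqs)
    states = {tree.root: root_states.astype(np.int16)}
    realized: dict[str, dict[str, int]] = {}
    eig_cache: dict[float, _EigGenerator] = {}
    q_cache: dict[float, np.ndarray] = {}
    # preorder = reversed postorder
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        parent_states = states[tree.parent[node]]
        t = float(tree.lengths[node])
        child = np.empty(n_codons, dtype=np.int16)
        n_syn = n_non = 0
        for k in range(n_class):
            mask = site_class == k
            if not mask.any():
                continue
            om = float(class_branch_omegas[k, node])
            if gillespie:
                if om not in q_cache:
                    q_cache[om] = _rate_matrix(spec.kappa, spec.freqs, om)
                sub, s_k, n_k = _gillespie_branch(
                    q_cache[om], t, parent_states[mask], rng
                )
                child[mask] = sub
                n_syn += s_k
                n_non += n_k
            else:
                if om not in eig_cache:
                    eig_cache[om] = _EigGenerator(spec.kappa, spec.freqs, om)
                child[mask] = _sample_states(
                    eig_cache[om].P(t), parent_states[mask], rng
                )
        states[node] = child
        if gillespie:
            realized[tree.labels[node]] = {"syn": n_syn, "nonsyn": n_non}
    taxa = tree.tip_labels
    seqs = [
        "".join(CODONS[s] for s in states[tree.tip_index[t]]) for t in taxa
    ]
    alignment = CodonAlignment(taxa=taxa, sequences=seqs, gene_label=gene_label)
    _, class_omegas = _expand_structure(spec, tree)
    site_omega = class_omegas[site_class, tree.branch_ids()[0]]
    struct = spec.omega_structure
    truth = SimulationTruth(
        model_id=(
            struct.model_id if isinstance(struct, SiteMixtureSpec)
            else ("branch-partition" if isinstance(struct, dict) else "M0")
        ),
        kappa=spec.kappa,
        freq_model=spec.freq_model,
        omega_structure=(
            {
                "classes": struct.classes, "beta": struct.beta,
                "beta_weight": struct.beta_weight, "ncat": struct.ncat,
            }
            if isinstance(struct, SiteMixtureSpec)
            else (
                {str(k): v for k, v in struct.items()}
                if isinstance(struct, dict) else float(struct)
            )
        ),
        site_classes=site_class.tolist() if n_class > 1 else None,
        site_omegas=site_omega.tolist() if n_class > 1 else None,
        newick=tree.to_newick(),
        seed=seed,
        n_codons=n_codons,
        realized_counts=realized or None,
    )
    return alignment, truth


def phylo_covariance(tree: Phylogeny, alpha: float, taxa: list[str]) -> np.ndarray:
    """Exponential-decay correlation matrix C_ij = exp(-alpha * d_ij)."""
    D = tree.patristic_distances(taxa)
    return np.exp(-alpha * D)


def simulate_traits(
    tree: Phylogeny,
    alpha: float,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    predictor_sd: float = 1.0,
) -> pd.DataFrame:
    """Bivariate species traits with phylogenetic covariance.

    Both the predictor x and the residual noise are multivariate normal
    with correlation exp(-alpha * d_ij) (patristic distance d); the
    response is ``intercept + slope * x + noise``.  With predictor_sd = 1
    the population GLS correlation is slope / sqrt(slope^2 + noise_sd^2).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    taxa = tree.tip_labels
    C = phylo_covariance(tree, alpha, taxa)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(taxa)))
    x = predictor_sd * (L @ rng.standard_normal(len(taxa)))
    eps = noise_sd * (L @ rng.standard_normal(len(taxa)))
    y = intercept + slope * x + eps
    return pd.DataFrame({"species": taxa, "x": x, "y": y})


# -------------------------------------------------------------- fixtures

# the generator's stated world: clade regimes mirror the three outcomes of
# the clade analysis (positive foreground, relaxed foreground at omega=1,
# uniform purifying background), protamine-scale alignment lengths, and
# rodent-plausible allometry for the trait table.
_FIXTURE_PARAMS = {
    "clade_positive": {"omega_fg": 2.44, "omega_bg": 0.3},
    "clade_relaxed": {"omega_fg": 1.0, "omega_bg": 0.3},
    "neutral": {"omega": 0.3},
    "n_codons": 165,
    "kappa": 2.0,
    "trait_alpha": 8.17,
    "trait_correlation": -0.574,
    "allometry": {"a": 0.031, "b": 0.77},
}


def _f3x4_freqs() -> np.ndarray:
    """A fixed, mildly GC-skewed F3X4 frequency vector for simulation."""
    nt = np.array([
        [0.30, 0.20, 0.30, 0.20],
        [0.25, 0.25, 0.30, 0.20],
        [0.20, 0.30, 0.30, 0.20],
    ])
    f = (
        nt[0, _codon_nts()[:, 0]] * nt[1, _codon_nts()[:, 1]]
        * nt[2, _codon_nts()[:, 2]]
    )
    return f / f.sum()


def _codon_nts() -> np.ndarray:
    from .codon_model import _CODON_NTS
    return _CODON_NTS


def make_fixture_set(out_dir, seed: int = 2011) -> dict[str, Path]:
    """Write a self-contained fixture bundle (FASTA + Newick + TSV + truth).

    Emits the clade tree, alignments simulated under the three clade
    regimes, a study-tree alignment for site analysis, a trait table and
    truth JSONs.  Deterministic in ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    ctree = clade_tree()
    stree = study_tree()
    ttree = trait_tree()
    for name, tr in [("clade", ctree), ("study", stree), ("traits", ttree)]:
        p = out / f"{name}.nwk"
        p.write_text(tr.to_newick() + "\n")
        files[f"{name}_tree"] = p

    freqs = _f3x4_freqs()
    kappa = _FIXTURE_PARAMS["kappa"]
    n_codons = _FIXTURE_PARAMS["n_codons"]
    fg = ctree.clade_branches(CRICETIDAE_TAXA, include_stem=True)
    for i, regime in enumerate(["clade_positive", "clade_relaxed", "neutral"]):
        pars = _FIXTURE_PARAMS[regime]
        if "omega" in pars:
            struct: float | dict = pars["omega"]
            tr = stree
        else:
            struct = {
                b: pars["omega_fg"] if b in fg else pars["omega_bg"]
                for b in ctree.branch_ids()
            }
            tr = ctree
        spec = CodonModelSpec(kappa, freqs, struct, "F3X4")
        aln, truth = simulate_codon_alignment(
            tr, spec, n_codons, seed=seed + i, gene_label=regime
        )
        fa = out / f"{regime}.fasta"
        write_fasta(aln, fa)
        truth.to_json(out / f"{regime}.truth.json")
        files[regime] = fa

    corr = _FIXTURE_PARAMS["trait_correlation"]
    slope = corr / np.sqrt(1 - corr**2)  # noise_sd = 1
    traits = simulate_traits(
        ttree, alpha=_FIXTURE_PARAMS["trait_alpha"], slope=slope,
        intercept=1.0, noise_sd=1.0, seed=seed + 10,
    )
    # dress the simulated predictor as a relative-testes-mass world:
    # body mass lognormal, testes mass from the allometry times the ratio
    rng = np.random.default_rng(seed + 11)
    a, b = _FIXTURE_PARAMS["allometry"]["a"], _FIXTURE_PARAMS["allometry"]["b"]
    body = np.exp(rng.normal(3.5, 0.8, size=len(traits)))
    rtm = np.exp(0.4 * traits["x"].to_numpy())  # positive ratio scale
    testes = a * body**b * rtm
    trait_table = pd.DataFrame({
        "species": traits["species"],
        "body_mass_g": np.round(body, 3),
        "testes_mass_g": np.round(testes, 5),
        "omega_path_sim": np.round(traits["y"].to_numpy(), 5),
    })
    tsv = out / "traits.tsv"
    trait_table.to_csv(tsv, sep="\t", index=False)
    files["traits"] = tsv
    meta = {
        "seed": seed,
        "params": {
            k: v for k, v in _FIXTURE_PARAMS.items()
        },
    }
    (out / "fixtures.json").write_text(json.dumps(meta, indent=1, default=str))
    return files
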