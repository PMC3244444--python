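"""End-to-end analysis orchestration.

Reproduces the analysis surface on any input bundle: integrity screening
(pseudogene exclusion), optional precursor splitting, the clade decision
(one-ratio / fixed / free two-ratio), the site-model suite with BEB and
domain profiling, free-ratio root-to-tip omega, and pGLS against relative
testes mass.  Every report embeds the config hash and seed; outputs are
TSV/JSON twins, diffable and deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, domains, rate_aggregation, selection_tests, seqio
from .seqio import CodonAlignment, DomainBoundary
from .trees import Phylogeny

__all__ = ["RunConfig", "run_full_analysis", "StageError"]

log = logging.getLogger("protsel")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class GeneConfig:
    alignment: str
    clade_alignment: str | None = None
    boundary: dict | None = None          # {"cleaved": [0,n], "mature": [n,m]}
    kinases: list[str] = field(default_factory=lambda: ["PKC", "PKA", "CK2"])
    cleavage_sites: list[int] = field(default_factory=list)
    reference: str | None = None


@dataclass
class RunConfig:
    """Validated run configuration; fully serialised into every report."""

    seed: int
    out_dir: str
    genes: dict[str, GeneConfig]
    study_tree: str | None = None
    clade_tree: str | None = None
    trait_tree: str | None = None
    foreground: list[str] = field(default_factory=list)
    traits_path: str | None = None
    allometry: dict | None = None         # {"a": ..., "b": ...}
    freq_model: str = "F3X4"
    ncat: int = 10
    cleandata: bool = True
    include_stem: bool = True
    identity_floor: float | None = 30.0
    optimize_branch_lengths: bool = True
    n_starts: int = 1
    exclude_override: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genes = {
            name: GeneConfig(**g) for name, g in raw.pop("genes", {}).items()
        }
        cfg = cls(genes=genes, **raw)
        if not cfg.genes:
            raise ValueError("config lists no genes")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = {"config_hash": cfg.digest(), "seed": cfg.seed, **payload}
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    return str(x)


def _lrt_dict(t: selection_tests.LRTResult) -> dict:
    return {
        "null": t.model_null, "alt": t.model_alt, "2dl": t.two_delta_l,
        "df": t.df, "p": t.p_value, "verdict": t.verdict,
    }


def _integrity_stage(
    name: str, aln: CodonAlignment, cfg: RunConfig, out: Path
) -> CodonAlignment:
    """Flag and drop dysfunctional sequences (overridable per config)."""
    dropped, report_rows = [], []
    refs = [aln.translate(t).replace("-", "") for t in aln.taxa]
    for i, taxon in enumerate(aln.taxa):
        others = [r for j, r in enumerate(refs) if j != i and r]
        rep = seqio.integrity_check(
            aln.sequences[i].replace("-", ""),
            reference_orthologues=others,
            identity_floor=cfg.identity_floor,
        )
        report_rows.append(
            {"taxon": taxon, "status": rep.status,
             "criteria": ";".join(rep.criteria),
             "best_identity": rep.best_identity}
        )
        if rep.status == "dysfunctional":
            dropped.append(taxon)
    keep_anyway = set(cfg.exclude_override.get(name, []))
    dropped = [t for t in dropped if t not in keep_anyway]
    pd.DataFrame(report_rows).to_csv(
        out / f"{name}.integrity.tsv", sep="\t", index=False
    )
    if dropped:
        log.info("%s: excluding dysfunctional taxa %s", name, dropped)
        aln = aln.drop_taxa(set(dropped))
    return aln


def _common_tree(tree_path: str, aln: CodonAlignment):
    """Restrict a tree and alignment to their shared taxa."""
    tree = Phylogeny.from_newick(tree_path)
    common = [t for t in tree.tip_labels if t in set(aln.taxa)]
    if set(common) != set(tree.tip_labels):
        tree = tree.retain_taxa(common)
    return tree, aln.drop_taxa(set(aln.taxa) - set(common))


def _clade_stage(name, aln, cfg: RunConfig, out: Path) -> dict:
    tree, aln = _common_tree(cfg.clade_tree, aln)
    foreground = [t for t in cfg.foreground if t in set(tree.tip_labels)]
    m1, m2, m3 = selection_tests.fit_clade_suite(
        aln, tree, foreground, include_stem=cfg.include_stem,
        freq_model=cfg.freq_model,
        optimize_branch_lengths=cfg.optimize_branch_lengths,
        cleandata=cfg.cleandata, n_starts=cfg.n_starts, seed=cfg.seed,
    )
    decision = selection_tests.classify_clade(m1, m2, m3)
    payload = {
        "gene": name,
        "omega_foreground": decision.foreground_omega,
        "omega_background": m3.params["omega_bg"],
        "label": decision.label,
        "lnL": {"m1": m1.lnL, "m2": m2.lnL, "m3": m3.lnL},
        "lrt_m1_vs_m3": _lrt_dict(decision.lrt_m1_vs_m3),
        "lrt_m2_vs_m3": _lrt_dict(decision.lrt_m2_vs_m3),
        "include_stem": cfg.include_stem,
    }
    _write_json(out / f"{name}.clade.json", payload, cfg)
    return payload


def _site_stage(name, aln, gene: GeneConfig, cfg: RunConfig, out: Path) -> dict:
    tree, aln = _common_tree(cfg.study_tree, aln)
    suite = selection_tests.fit_site_suite(
        aln, tree, freq_model=cfg.freq_model, ncat=cfg.ncat,
        optimize_branch_lengths=cfg.optimize_branch_lengths,
        cleandata=cfg.cleandata, n_starts=cfg.n_starts, seed=cfg.seed,
    )
    beb_model = "M2a" if suite.lrt_m1a_m2a.significant else "M1a"
    posterior = selection_tests.beb_classify(
        aln, tree, suite.fits[beb_model], cleandata=cfg.cleandata
    )
    # domain annotation on the reference (or first) taxon's residues
    ref = gene.reference or aln.taxa[0]
    aa = aln.translate(ref)
    annot = domains.DomainAnnotation()
    annot.add(domains.scan_anchoring(aa))
    annot.add(domains.scan_phospho(aa, set(gene.kinases)))
    if gene.cleavage_sites:
        annot.add(domains.map_configured_sites(
            aln, gene.cleavage_sites, "cleavage", ref
        ))
    profile = domains.profile_regions(posterior, annot)
    summary = selection_tests.summarize_site_classes(
        posterior, annot, alignment=aln, reference=ref
    )
    pd.DataFrame(
        annot.to_bed_rows(ref),
        columns=["seq", "start", "end", "type", "source"],
    ).to_csv(out / f"{name}.domains.tsv", sep="\t", index=False)
    site_table = pd.DataFrame({
        "site": np.arange(posterior.n_sites) + 1,
        "class1": posterior.class_probs[:, 0],
        "class2": posterior.class_probs[:, 1],
        "class3": posterior.class_probs[:, 2],
        "mean_omega": posterior.mean_omega,
        "se_omega": posterior.se_omega,
        "assigned": posterior.assigned_class,
    })
    site_table.to_csv(out / f"{name}.sites.tsv", sep="\t", index=False)
    payload = {
        "gene": name,
        "lnL": {m: f.lnL for m, f in suite.fits.items()},
        "params": {m: f.params for m, f in suite.fits.items()},
        "lrt_m1a_m2a": _lrt_dict(suite.lrt_m1a_m2a),
        "lrt_m7_m8": _lrt_dict(suite.lrt_m7_m8),
        "designations": [suite.designation_m1a_m2a, suite.designation_m7_m8],
        "beb_model": beb_model,
        "class_percent": summary.overall,
        "per_region": summary.per_region,
        "positively_selected": summary.positively_selected,
        "domain_profile": profile,
    }
    _write_json(out / f"{name}.sites.json", payload, cfg)
    return payload


def _roottip_stage(name, aln, cfg: RunConfig, out: Path) -> pd.DataFrame:
    tree, aln = _common_tree(cfg.study_tree, aln)
    fr = rate_aggregation.free_ratio_fit(
        aln, tree, freq_model=cfg.freq_model,
        optimize_branch_lengths=cfg.optimize_branch_lengths,
        cleandata=cfg.cleandata, n_starts=cfg.n_starts, seed=cfg.seed,
    )
    table = rate_aggregation.root_to_tip_table(fr, tree)
    table = table[table["species"].isin(aln.taxa)]
    table.to_csv(out / f"{name}.roottip.tsv", sep="\t", index=False)
    return table


def _pgls_stage(name, roottip: pd.DataFrame, cfg: RunConfig, out: Path) -> dict:
    tree = Phylogeny.from_newick(cfg.trait_tree)
    traits = pd.read_csv(cfg.traits_path, sep="\t")
    a, b = cfg.allometry["a"], cfg.allometry["b"]
    traits["rtm"] = comparative.relative_testes_mass(
        traits["body_mass_g"], traits["testes_mass_g"], a, b
    )
    x = traits.set_index("species")["rtm"]
    y = roottip.set_index("species")["omega_path"].dropna()
    fit = comparative.pgls_fit(tree, x, y)
    star = comparative.significance_by_ci(fit)
    payload = {
        "gene": name, "n": fit.n, "ci_lo": fit.ci[0], "ci_hi": fit.ci[1],
        "lnL": fit.lnL, "alpha": fit.alpha, "slope": fit.slope,
        "correlation": fit.correlation, "significance": star,
    }
    _write_json(out / f"{name}.pgls.json", payload, cfg)
    pd.DataFrame([payload]).to_csv(
        out / f"{name}.pgls.tsv", sep="\t", index=False
    )
    return payload


def run_full_analysis(config: RunConfig) -> dict:
    """Run every configured stage for every gene; returns the report bundle.

    Stage order per gene: integrity screen -> optional precursor split ->
    clade suite + decision -> site suite + BEB + domain profiling ->
    free-ratio root-to-tip omega -> pGLS.  A stage failure raises
    :class:`StageError`; previously written outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps({"config_hash": config.digest(), **config.to_dict()},
                   indent=1, default=_jsonable)
    )
    bundle: dict[str, dict] = {}
    for gene_name, gene in config.genes.items():
        report: dict = {}
        try:
            aln = seqio.read_fasta(gene.alignment, gene_label=gene_name)
            aln = _integrity_stage(gene_name, aln, config, out)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"{gene_name}:integrity", e) from e
        parts: dict[str, CodonAlignment] = {gene_name: aln}
        if gene.boundary:
            try:
                bd = DomainBoundary(
                    tuple(gene.boundary["cleaved"]),
                    tuple(gene.boundary["mature"]),
                )
                cleaved, mature = seqio.split_prm2(aln, bd)
                parts = {
                    f"cleaved-{gene_name}": cleaved,
                    f"mature-{gene_name}": mature,
                }
            except Exception as e:  # noqa: BLE001
                raise StageError(f"{gene_name}:split", e) from e
        for part_name, part_aln in parts.items():
            part_report: dict = {}
            if config.clade_tree and config.foreground:
                clade_aln = part_aln
                if gene.clade_alignment:
                    clade_aln = seqio.read_fasta(gene.clade_alignment)
                try:
                    part_report["clade"] = _clade_stage(
                        part_name, clade_aln, config, out
                    )
                except Exception as e:  # noqa: BLE001
                    raise StageError(f"{part_name}:clade", e) from e
            if config.study_tree:
                try:
                    part_report["sites"] = _site_stage(
                        part_name, part_aln, gene, config, out
                    )
                except Exception as e:  # noqa: BLE001
                    raise StageError(f"{part_name}:sites", e) from e
                try:
                    roottip = _roottip_stage(part_name, part_aln, config, out)
                except Exception as e:  # noqa: BLE001
                    raise StageError(f"{part_name}:roottip", e) from e
                if config.traits_path and config.trait_tree:
                    try:
                        part_report["pgls"] = _pgls_stage(
                            part_name, roottip, config, out
                        )
                    except Exception as e:  # noqa: BLE001
                        raise StageError(f"{part_name}:pgls", e) from e
            report[part_name] = part_report
        bundle[gene_name] = report
    _write_json(out / "report.json", {"genes": bundle}, config)
    return bundle
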