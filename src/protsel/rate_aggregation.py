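"""Per-species cumulative omega from a free-ratio fit.

Species-level selective pressure is summarised by summing the expected
nonsynonymous (dN) and synonymous (dS) substitutions over every branch on
the unique root-to-tip path and taking the RATIO OF THE SUMS — not the
mean of per-branch ratios, which weights short and long branches equally
and is not what accumulates over a lineage's history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .codon_model import FitResult, fit
from .seqio import CodonAlignment
from .trees import Phylogeny

__all__ = ["PathOmega", "free_ratio_fit", "root_to_tip_omega", "root_to_tip_table"]


@dataclass
class PathOmega:
    """Cumulative root-to-tip substitution summary for one species."""

    species: str
    sum_dN: float
    sum_dS: float
    omega_path: float | None    # None when sum_dS == 0 (undefined)

    @property
    def defined(self) -> bool:
        return self.omega_path is not None


def free_ratio_fit(
    alignment: CodonAlignment, tree: Phylogeny, **fit_kwargs
) -> FitResult:
    """Fit an independent omega on every branch (free-ratio model)."""
    return fit(alignment, tree, "free-ratio", **fit_kwargs)


def root_to_tip_omega(
    fit_result: FitResult, tree: Phylogeny, species: str
) -> PathOmega:
    """Sum dN and dS along the root-to-tip path; ratio of the sums."""
    path = tree.root_to_tip_path(species)
    table = fit_result.branch_table.set_index("node")
    sum_dN = float(table.loc[path, "dN"].sum())
    sum_dS = float(table.loc[path, "dS"].sum())
    if sum_dS > 0:
        omega = sum_dN / sum_dS
    else:
        warnings.warn(
            f"{species}: zero synonymous substitutions on root-to-tip path; "
            "omega_path undefined", stacklevel=2,
        )
        omega = None
    return PathOmega(species=species, sum_dN=sum_dN, sum_dS=sum_dS,
                     omega_path=omega)


def root_to_tip_table(fit_result: FitResult, tree: Phylogeny) -> pd.DataFrame:
    """Root-to-tip summary for every tip; undefined ratios become NaN."""
    rows = []
    for sp in tree.tip_labels:
        po = root_to_tip_omega(fit_result, tree, sp)
        rows.append({
            "species": po.species, "sum_dN": po.sum_dN, "sum_dS": po.sum_dS,
            "omega_path": po.omega_path if po.defined else float("nan"),
        })
    return pd.DataFrame(rows)
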