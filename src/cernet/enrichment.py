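"""Module-to-module overlap enrichment between two conditions.

Each module of condition A is tested against each module of condition B
for over-representation of shared genes, relative to a background universe
(by default the union of both co-expression networks' node sets). The test
is the one-sided upper-tail hypergeometric probability

    p = P(X >= k),   X ~ Hypergeometric(N, |A|, |B|)

which equals Fisher's exact test (alternative="greater") on the 2x2 table

    [[k, |A|-k], [|B|-k, N-|A|-|B|+k]].

P-values are Benjamini–Hochberg adjusted across the full module-by-module
family, and the adjusted values drive a three-tier significance code:
``***`` (q < 0.001, green), ``**`` (q < 0.01, gold), ``*`` (q < 0.05,
yellow), else ``NE`` (not enriched, drawn as ``+``).

Display order follows the canonical WGCNA colour sequence (turquoise,
blue, brown, ...) so that the largest, most reproducible modules sit at
the bottom-left corner of the dot plot.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    CoexpressionNetwork,
    ModulePartition,
    UNASSIGNED_MODULE,
    background_union,
)

logger = logging.getLogger("cernet")

#: WGCNA's canonical module colour sequence (modules are named in
#: decreasing size order along this list).
WGCNA_COLOR_ORDER: Tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta",
)

DEFAULT_TIERS: Tuple[float, float, float] = (0.001, 0.01, 0.05)

_TIER_STYLE = {
    "***": "green",
    "**": "gold",
    "*": "yellow",
    "NE": "+",
}


@dataclass
class Background:
    """Gene universe for the hypergeometric test."""

    genes: Set[str]
    mode: str = "union_of_networks"  # or "explicit_list"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("background universe is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentCell:
    module_a: str
    module_b: str
    overlap_k: int
    size_a: int
    size_b: int
    background_n: int
    p_value: float
    adjusted_p: float = float("nan")
    tier: str = "NE"


@dataclass
class EnrichmentTable:
    cells: List[EnrichmentCell]
    row_order: List[str]
    col_order: List[str]
    condition_a: str = ""
    condition_b: str = ""

    def to_frame(self) -> pd.DataFrame:
        """All cells as a DataFrame in row-major display order."""
        index = {
            (c.module_a, c.module_b): c for c in self.cells
        }
        rows = []
        for ma in self.row_order:
            for mb in self.col_order:
                c = index[(ma, mb)]
                rows.append(
                    {
                        "module_a": c.module_a,
                        "module_b": c.module_b,
                        "k": c.overlap_k,
                        "size_a": c.size_a,
                        "size_b": c.size_b,
                        "N": c.background_n,
                        "p": c.p_value,
                        "adjusted_p": c.adjusted_p,
                        "tier": c.tier,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def cell(self, module_a: str, module_b: str) -> EnrichmentCell:
        for c in self.cells:
            if c.module_a == module_a and c.module_b == module_b:
                return c
        raise KeyError((module_a, module_b))


def overlap_contingency(
    module_a_genes: Set[str], module_b_genes: Set[str], background: Background
) -> Tuple[int, int, int, int]:
    """2x2 table (k, |A|-k, |B|-k, N-|A|-|B|+k) for the overlap test."""
    for g in module_a_genes | module_b_genes:
        if g not in background.genes:
            raise ValueError(f"module gene {g!r} is outside the background universe")
    k = len(module_a_genes & module_b_genes)
    a, b, n = len(module_a_genes), len(module_b_genes), len(background)
    return (k, a - k, b - k, n - a - b + k)


def hypergeom_overlap_p(
    k: int, size_a: int, size_b: int, n_background: int
) -> float:
    """One-sided upper-tail hypergeometric p-value P(X >= k)."""
    if not (0 <= k <= min(size_a, size_b)):
        raise ValueError(
            f"inconsistent counts: k={k}, size_a={size_a}, size_b={size_b}"
        )
    if max(size_a, size_b) > n_background:
        raise ValueError(
            f"module size exceeds background: sizes ({size_a}, {size_b}), "
            f"N={n_background}"
        )
    # sf(k-1) = P(X >= k); exact for k=0 -> 1.0
    p = float(hypergeom.sf(k - 1, n_background, size_a, size_b))
    return min(p, 1.0)


def adjust_pvalues(
    p_values: Sequence[float], method: str = "fdr_bh"
) -> List[float]:
    """Multiple-testing adjustment (Benjamini–Hochberg step-up by default).

    Returns adjusted values in the input order; each lies in [p, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method=method)[1]
    return [float(q) for q in adjusted]


def significance_tier(
    adjusted_p: float, thresholds: Sequence[float] = DEFAULT_TIERS
) -> Tuple[str, str]:
    """Map an adjusted p-value to (tier code, display colour/marker).

    Strict inequalities: q < t1 -> ("***", green); q < t2 -> ("**", gold);
    q < t3 -> ("*", yellow); otherwise ("NE", "+").
    """
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError(f"tier thresholds must increase: {thresholds}")
    if adjusted_p < t1:
        tier = "***"
    elif adjusted_p < t2:
        tier = "**"
    elif adjusted_p < t3:
        tier = "*"
    else:
        tier = "NE"
    return tier, _TIER_STYLE[tier]


def _canonical_rank(label: str) -> Optional[int]:
    key = re.sub(r"[^a-z0-9]", "", label.lower())
    try:
        return WGCNA_COLOR_ORDER.index(key)
    except ValueError:
        return None


def module_display_order(partition: ModulePartition) -> List[str]:
    """Module labels in dot-plot display order.

    Canonical WGCNA colours come first in their canonical sequence
    (turquoise, blue, brown, ...); remaining labels follow, ordered by
    descending module size and then lexicographically.
    """
    sizes = partition.module_sizes()
    canonical = sorted(
        (m for m in sizes if _canonical_rank(m) is not None), key=_canonical_rank
    )
    other = sorted(
        (m for m in sizes if _canonical_rank(m) is None),
        key=lambda m: (-sizes[m], m),
    )
    return canonical + other


def module_enrichment(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    background: Optional[Background] = None,
    exclude_unassigned: bool = True,
    thresholds: Sequence[float] = DEFAULT_TIERS,
    adjust_method: str = "fdr_bh",
) -> EnrichmentTable:
    """All-pairs module overlap enrichment between two conditions.

    Module memberships are intersected with the background before the test
    (a module emptied by the restriction is computed with k = 0 and a
    warning). Adjustment is applied across the whole table as one family.
    """
    if background is None:
        background = Background(background_union(net_a, net_b))
    include = not exclude_unassigned
    mods_a = net_a.partition.modules(include_unassigned=include)
    mods_b = net_b.partition.modules(include_unassigned=include)
    if not mods_a or not mods_b:
        raise ValueError("both partitions must contain at least one module")

    n = len(background)
    cells: List[EnrichmentCell] = []
    for ma, genes_a in mods_a.items():
        ga = genes_a & background.genes
        if genes_a and not ga:
            logger.warning("module %s (A) empty after background restriction", ma)
        for mb, genes_b in mods_b.items():
            gb = genes_b & background.genes
            if genes_b and not gb:
                logger.warning(
                    "module %s (B) empty after background restriction", mb
                )
            k = len(ga & gb)
            p = hypergeom_overlap_p(k, len(ga), len(gb), n)
            cells.append(
                EnrichmentCell(
                    module_a=ma,
                    module_b=mb,
                    overlap_k=k,
                    size_a=len(ga),
                    size_b=len(gb),
                    background_n=n,
                    p_value=p,
                )
            )
    adjusted = adjust_pvalues([c.p_value for c in cells], method=adjust_method)
    for c, q in zip(cells, adjusted):
        c.adjusted_p = q
        c.tier = significance_tier(q, thresholds)[0]
    table = EnrichmentTable(
        cells=cells,
        row_order=module_display_order(net_a.partition),
        col_order=module_display_order(net_b.partition),
        condition_a=net_a.condition_name,
        condition_b=net_b.condition_name,
    )
    # orders may include the unassigned module even when it was excluded
    if exclude_unassigned:
        table.row_order = [m for m in table.row_order if m in mods_a]
        table.col_order = [m for m in table.col_order if m in mods_b]
    return table


def enrichment_dotplot(
    table: EnrichmentTable, path, tsv_path=None
) -> pd.DataFrame:
    """Render the enrichment dot plot and write the ordered cell TSV.

    The first modules of each display order sit at the bottom-left corner.
    Significant cells are drawn as coloured dots (green/gold/yellow for
    ***/**/*), non-enriched cells as ``+``. Returns the cell DataFrame.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not table.cells:
        raise ValueError("enrichment table is empty")
    df = table.to_frame()
    if tsv_path is None:
        tsv_path = str(path).rsplit(".", 1)[0] + ".tsv"
    df.to_csv(tsv_path, sep="\t", index=False)

    rows, cols = table.row_order, table.col_order
    yi = {m: i for i, m in enumerate(rows)}
    xi = {m: i for i, m in enumerate(cols)}
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.45 * len(cols) + 1.8), max(3.0, 0.45 * len(rows) + 1.5))
    )
    for c in table.cells:
        x, y = xi[c.module_b], yi[c.module_a]
        colour = _TIER_STYLE[c.tier]
        if c.tier == "NE":
            ax.plot(x, y, marker="+", color="grey", markersize=7)
        else:
            size = 40 + 20 * c.tier.count("*")
            ax.scatter([x], [y], s=size, color=colour, edgecolors="black",
                       linewidths=0.4, zorder=3)
    ax.set_xticks(range(len(cols)), cols, rotation=90)
    ax.set_yticks(range(len(rows)), rows)
    ax.set_xlim(-0.5, len(cols) - 0.5)
    ax.set_ylim(-0.5, len(rows) - 0.5)
    ax.set_xlabel(table.condition_b or "condition B")
    ax.set_ylabel(table.condition_a or "condition A")
    ax.set_title("module overlap enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return df
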