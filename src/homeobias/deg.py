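"""Expression filtering and differential-expression calling.

A gene is "expressed" when its replicate-mean FPKM reaches the cutoff
(default 1, the conventional empirical floor for FPKM data).  A homoeolog
pair enters the pair-level analyses when it is expressed in parent A, in
parent C, or at the pair-total level in the polyploid (per-replicate
A_n + C_n).

DEGs between a polyploid subgenome and its diploid parent are called
per gene with a two-sample t-test on log2(FPKM + pseudocount) replicate
values (variance stabilization), BH-adjusted per subgenome comparison,
and thresholded at q <= fdr_cutoff and |log2FC| >= lfc_cutoff, the fold
change being computed on pseudocounted replicate means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError, LookupMismatchError
from .io import ExpressionTable
from .stats import bh_fdr, log2_fold_change, t_test_many

DEFAULT_FPKM_CUTOFF = 1.0
DEFAULT_FDR_CUTOFF = 0.05
DEFAULT_LFC_CUTOFF = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


def filter_expressed(table: ExpressionTable, cutoff: float = DEFAULT_FPKM_CUTOFF) -> pd.Series:
    """Boolean per-gene flag: replicate-mean FPKM >= cutoff."""
    if cutoff < 0:
        raise InvalidInputError("cutoff must be >= 0")
    return table.means() >= cutoff


def expressed_pairs(
    pairs: pd.DataFrame,
    parent_a: ExpressionTable,
    parent_c: ExpressionTable,
    polyploid: ExpressionTable,
    cutoff: float = DEFAULT_FPKM_CUTOFF,
) -> pd.DataFrame:
    """Subset of ``pairs`` expressed in at least one of the three species.

    Parent expression is per the gene's replicate mean; polyploid
    expression uses the pair total (per-replicate A_n + C_n) so that two
    half-expressed homoeologs jointly clearing the cutoff retain the pair.
    """
    missing = []
    for col, table in (("gene_id_A", parent_a), ("gene_id_C", parent_c)):
        missing += sorted(set(pairs[col]) - set(table.data.index))
    missing += sorted(
        (set(pairs["gene_id_A"]) | set(pairs["gene_id_C"])) - set(polyploid.data.index)
    )
    if missing:
        raise LookupMismatchError(
            f"pair genes missing from tables: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    mean_a = parent_a.means().loc[pairs["gene_id_A"]].to_numpy()
    mean_c = parent_c.means().loc[pairs["gene_id_C"]].to_numpy()
    poly_total = (
        polyploid.data.loc[pairs["gene_id_A"]].to_numpy()
        + polyploid.data.loc[pairs["gene_id_C"]].to_numpy()
    )
    mean_poly = poly_total.mean(axis=1)
    keep = (mean_a >= cutoff) | (mean_c >= cutoff) | (mean_poly >= cutoff)
    return pairs.loc[keep].reset_index(drop=True)


def call_degs(
    polyploid_sub: ExpressionTable | pd.DataFrame,
    parent: ExpressionTable | pd.DataFrame,
    subgenome: str,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    expression_cutoff: float = DEFAULT_FPKM_CUTOFF,
) -> pd.DataFrame:
    """Call DEGs polyploid-subgenome vs parent for 1:1 matched genes.

    Only genes expressed (replicate mean >= expression_cutoff) in at least
    one of the two tables are tested; BH runs across the tested genes of
    this comparison.  ``status`` is 'up' (higher in the polyploid),
    'down', or 'not_de'.
    """
    poly = polyploid_sub.data if isinstance(polyploid_sub, ExpressionTable) else polyploid_sub
    par = parent.data if isinstance(parent, ExpressionTable) else parent
    common = poly.index.intersection(par.index)
    if len(common) == 0:
        raise InvalidInputError("no genes shared between polyploid subgenome and parent")
    if poly.shape[1] < 2 or par.shape[1] < 2:
        raise InvalidInputError("need >= 2 replicates per table")
    poly = poly.loc[common]
    par = par.loc[common]
    mean_poly = poly.mean(axis=1).to_numpy()
    mean_par = par.mean(axis=1).to_numpy()
    tested = (mean_poly >= expression_cutoff) | (mean_par >= expression_cutoff)
    if not tested.any():
        raise InvalidInputError("no genes pass the expression cutoff")

    Xp = np.log2(poly.to_numpy()[tested] + pseudocount)
    Xa = np.log2(par.to_numpy()[tested] + pseudocount)
    p, _, _, _ = t_test_many(Xp, Xa, alpha=fdr_cutoff)
    q = bh_fdr(p)
    lfc = log2_fold_change(mean_poly[tested], mean_par[tested], pseudocount)
    de = (q <= fdr_cutoff) & (np.abs(lfc) >= lfc_cutoff)
    status = np.where(de, np.where(lfc > 0, "up", "down"), "not_de")
    return pd.DataFrame(
        {
            "gene_id": common[tested],
            "subgenome": subgenome,
            "mean_polyploid": mean_poly[tested],
            "mean_parent": mean_par[tested],
            "log2fc": lfc,
            "p": p,
            "q": q,
            "status": status,
        }
    ).reset_index(drop=True)


def deg_summary(records: pd.DataFrame) -> dict:
    """Counts of up/down/not_de per subgenome plus overall totals."""
    out: dict = {"by_subgenome": {}, "total_tested": int(len(records))}
    for sub, grp in records.groupby("subgenome"):
        counts = grp["status"].value_counts()
        out["by_subgenome"][sub] = {
            "tested": int(len(grp)),
            "up": int(counts.get("up", 0)),
            "down": int(counts.get("down", 0)),
            "not_de": int(counts.get("not_de", 0)),
        }
    out["total_de"] = int((records["status"] != "not_de").sum())
    return out


def split_polyploid(polyploid: ExpressionTable) -> dict[str, ExpressionTable]:
    """Split a polyploid table into per-subgenome ExpressionTables."""
    if polyploid.subgenome is None:
        raise InvalidInputError("polyploid table lacks subgenome assignments")
    out = {}
    for tag in ("A", "C"):
        genes = polyploid.subgenome.index[polyploid.subgenome == tag]
        out[tag] = ExpressionTable(polyploid.data.loc[genes], "polyploid")
    return out
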