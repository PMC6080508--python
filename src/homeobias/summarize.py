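"""Count/proportion tables over classification outcomes, plus enrichment.

Every summary is a partition: strata counts must sum to the declared
denominator, and percentages are computed exactly from integer counts
with half-to-even rounding at one decimal (the convention of published
figure captions, e.g. 6170/16915 -> 36.5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .errors import InvalidInputError
from .stats import bh_fdr, hypergeom_tail

DEFAULT_ENRICH_FDR = 0.001

ELD_GROUPS = ("NoChange", "ELD_A", "ELD_C", "Additivity", "TransUp", "TransDown")
CATEGORY_ORDER = (
    "NoChange", "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
)


def percent_of(count: int, denominator: int) -> float:
    """count/denominator as a percent, half-to-even rounded to 1 decimal."""
    if denominator <= 0:
        raise InvalidInputError("denominator must be > 0")
    frac = Decimal(int(count)) * 100 / Decimal(int(denominator))
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


@dataclass
class SummaryTable:
    """Stratum -> count over a declared denominator."""

    counts: dict[str, int]
    denominator: int

    def __post_init__(self):
        if self.denominator <= 0:
            raise InvalidInputError("denominator must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise InvalidInputError("counts must be >= 0")
        if sum(self.counts.values()) != self.denominator:
            raise InvalidInputError(
                f"counts sum to {sum(self.counts.values())}, "
                f"declared denominator is {self.denominator}"
            )

    @classmethod
    def from_counts(cls, counts: dict[str, int], denominator: int | None = None):
        return cls(dict(counts), denominator if denominator is not None else sum(counts.values()))

    def percent(self, label: str) -> float:
        return percent_of(self.counts[label], self.denominator)

    def percents(self) -> dict[str, float]:
        return {k: self.percent(k) for k in self.counts}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percent(k) for k in self.counts],
                "denominator": self.denominator,
            }
        )


def _check_pairs(df: pd.DataFrame, what: str) -> None:
    if len(df) == 0:
        raise InvalidInputError(f"{what}: empty input")
    if df["pair_id"].duplicated().any():
        dups = df["pair_id"][df["pair_id"].duplicated()].head(5).tolist()
        raise InvalidInputError(f"{what}: duplicate pair_id {dups}")


def summarize_bias(bias: pd.DataFrame) -> dict[str, SummaryTable]:
    """Progeny-bias and transition tables over all expressed pairs.

    The three-way transition table folds 'switched' into 'novel' so that
    maintained/novel/reverted partition the total; the four-way table is
    also returned.
    """
    _check_pairs(bias, "bias results")
    n = len(bias)
    progeny = bias["progeny_state"].value_counts()
    progeny_table = SummaryTable(
        {
            "A_biased": int(progeny.get("A_gt", 0)),
            "C_biased": int(progeny.get("C_gt", 0)),
            "no_bias": int(progeny.get("EQ", 0)),
        },
        n,
    )
    tr = bias["transition"].value_counts()
    transition4 = SummaryTable(
        {k: int(tr.get(k, 0)) for k in ("maintained", "novel", "reverted", "switched")},
        n,
    )
    transition3 = SummaryTable(
        {
            "maintained": int(tr.get("maintained", 0)),
            "novel": int(tr.get("novel", 0)) + int(tr.get("switched", 0)),
            "reverted": int(tr.get("reverted", 0)),
        },
        n,
    )
    biased = progeny_table.counts["A_biased"] + progeny_table.counts["C_biased"]
    overall = SummaryTable({"biased": biased, "no_bias": n - biased}, n)
    return {
        "progeny": progeny_table,
        "transition": transition3,
        "transition4": transition4,
        "overall": overall,
    }


def summarize_eld(eld: pd.DataFrame) -> dict[str, SummaryTable]:
    """Group-level and per-category tables over all expressed pairs."""
    _check_pairs(eld, "ELD results")
    n = len(eld)
    grp = eld["group"].value_counts()
    cat = eld["category"].value_counts()
    return {
        "group": SummaryTable({g: int(grp.get(g, 0)) for g in ELD_GROUPS}, n),
        "category": SummaryTable({c: int(cat.get(c, 0)) for c in CATEGORY_ORDER}, n),
    }


def summarize_explain(explain: pd.DataFrame, eld: pd.DataFrame) -> dict:
    """Cross-tabs and mechanism totals for the ELD explanation analysis.

    Returns per-category 3x3 (change_A x change_C) cross-tabs, mechanism
    totals in the overlapping figure convention (the joint dominant-down/
    nondominant-up cell counts toward both mechanisms), the
    modified-homoeolog marginals, and the fraction of ELD pairs with at
    least one modified homoeolog.
    """
    _check_pairs(eld, "ELD results")
    eld_pairs = eld.loc[eld["group"].isin(["ELD_A", "ELD_C"]), "pair_id"]
    missing = sorted(set(eld_pairs) - set(explain["pair_id"]))
    if missing:
        raise InvalidInputError(
            f"explain results missing ELD pairs: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    if len(explain) and explain["pair_id"].duplicated().any():
        raise InvalidInputError("explain results: duplicate pair_id")
    n_eld = int(len(eld_pairs))
    sub = explain[explain["pair_id"].isin(set(eld_pairs))]

    crosstabs = {}
    mechanisms = {}
    levels = ["down", "unchanged", "up"]
    for category, grp in sub.groupby("category"):
        ct = pd.crosstab(grp["change_A"], grp["change_C"]).reindex(
            index=levels, columns=levels, fill_value=0
        )
        crosstabs[category] = ct
        mech = grp["mechanism"].value_counts()
        joint = int(mech.get("dominant_down_nondominant_up", 0))
        mechanisms[category] = {
            "dominant_down": int(mech.get("dominant_down", 0)) + joint,
            "nondominant_up": int(mech.get("nondominant_up", 0)) + joint,
            "nondominant_down": int(mech.get("nondominant_down", 0)),
            "both_down": int(mech.get("both_down", 0)),
            "none": int(mech.get("none", 0)),
            "other": int(mech.get("other", 0)),
        }
    a_modified = int((sub["change_A"] != "unchanged").sum())
    c_modified = int((sub["change_C"] != "unchanged").sum())
    neither = int(
        ((sub["change_A"] == "unchanged") & (sub["change_C"] == "unchanged")).sum()
    )
    modified = SummaryTable({"modified": n_eld - neither, "unmodified": neither}, n_eld)
    return {
        "crosstabs": crosstabs,
        "mechanisms": mechanisms,
        "a_modified": a_modified,
        "c_modified": c_modified,
        "neither_modified": neither,
        "modified_table": modified,
    }


def enrich(
    study,
    background,
    term_map: dict,
    fdr_cutoff: float = DEFAULT_ENRICH_FDR,
    blacklist=(),
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``study`` against ``background``.

    ``term_map`` maps term id -> (description, gene set), the GMT layout.
    Terms overlapping no study gene are excluded; q-values are BH across
    the tested terms; output sorted by (q, p, term).
    """
    study = set(study)
    background = set(background)
    if not study:
        raise InvalidInputError("study set is empty")
    stray = study - background
    if stray:
        raise InvalidInputError(
            f"study genes absent from background: {sorted(stray)[:10]}"
        )
    N = len(background)
    n = len(study)
    rows = []
    for term, (desc, genes) in term_map.items():
        if term in blacklist:
            continue
        K = len(genes & background)
        k = len(genes & study)
        if k == 0:
            continue
        rows.append((term, desc, k, n, K, N, hypergeom_tail(k, n, K, N)))
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "n", "K", "N", "p", "q", "enriched"]
        )
    out = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["q"] <= fdr_cutoff
    return out.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)
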