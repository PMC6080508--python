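"""Per-pair classification of duplicate-gene expression.

A homoeolog pair contributes four replicate vectors: the two diploid
parents (``A_r``, ``C_o``) and the two homoeolog copies in the
allopolyploid (``A_n``, ``C_n``).  Three layers of classification are
computed from ternary t-test outcomes at P <= alpha:

* **homoeolog expression bias** — which copy is preferentially expressed,
  in the parents (A_r vs C_o) and in the polyploid (A_n vs C_n), and how
  the state transitions (maintained / novel / reverted / switched);
* **expression-level dominance (ELD)** — the pair total S = A_n + C_n
  compared with each parent, yielding twelve categories covering no
  change, ELD toward either genome, additivity, and transgressive
  expression up or down;
* **explanation** — for ELD pairs, how each individual homoeolog moved
  relative to its own parent (A_n vs A_r, C_n vs C_o), condensed into a
  mechanism label (dominant copy down, nondominant copy up, ...).

``truth_label`` applies the same decision tables to exact means (equality
instead of a t-test), serving as the noise-free oracle for the simulator.

Categories use the conventional Roman-numeral layout of the twelve-state
framework: ELD_A = {IV, IX}, ELD_C = {II, XI}, additivity = {I, XII},
transgressive up = {V, VI, VIII}, transgressive down = {III, VII, X}.
Group labels are the authoritative output; numerals orient figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, LookupMismatchError
from .stats import (
    DEFAULT_ALPHA,
    REL_TOL,
    Direction,
    TestOutcome,
    t_test,
    t_test_many,
)

GROUP_OF_CATEGORY = {
    "NoChange": "NoChange",
    "IV": "ELD_A",
    "IX": "ELD_A",
    "II": "ELD_C",
    "XI": "ELD_C",
    "I": "Additivity",
    "XII": "Additivity",
    "V": "TransUp",
    "VI": "TransUp",
    "VIII": "TransUp",
    "III": "TransDown",
    "VII": "TransDown",
    "X": "TransDown",
}

ELD_DIRECTION_OF_CATEGORY = {
    "IV": "higher_parent",
    "II": "higher_parent",
    "IX": "lower_parent",
    "XI": "lower_parent",
}

#: expected A_r-vs-C_o direction code implied by each non-transgressive
#: category's geometry (transgressive subclasses are defined by that test)
_EXPECTED_DAC = {
    "NoChange": 0,
    "IV": 1,   # S = A_r > C_o
    "IX": -1,  # S = A_r < C_o
    "II": -1,  # S = C_o > A_r
    "XI": 1,   # S = C_o < A_r
    "I": -1,   # A_r < S < C_o
    "XII": 1,  # C_o < S < A_r
}

_TRANS_UP = {-1: "V", 0: "VI", 1: "VIII"}
_TRANS_DOWN = {-1: "III", 0: "VII", 1: "X"}

_BIAS_STATE = {-1: "C_gt", 0: "EQ", 1: "A_gt"}
_CHANGE = {-1: "down", 0: "unchanged", 1: "up"}

ELD_CATEGORIES = ("IV", "IX", "II", "XI")


def decide_category(d1: int, d2: int, d_ac: int) -> str:
    """Category from direction codes of (S vs A_r), (S vs C_o), (A_r vs C_o)."""
    key = (d1, d2)
    table = {
        (0, 0): "NoChange",
        (0, 1): "IV",
        (0, -1): "IX",
        (1, 0): "II",
        (-1, 0): "XI",
        (1, -1): "I",
        (-1, 1): "XII",
    }
    if key in table:
        return table[key]
    if key == (1, 1):
        return _TRANS_UP[d_ac]
    return _TRANS_DOWN[d_ac]


def transition_of(parent_state: str, progeny_state: str) -> str:
    if parent_state == progeny_state:
        return "maintained"
    if parent_state == "EQ":
        return "novel"
    if progeny_state == "EQ":
        return "reverted"
    return "switched"


def mechanism_of(category: str, change_A: str, change_C: str) -> str:
    """Condense the two homoeolog changes into a mechanism label.

    Dominant parent is the one the pair total matches: the A copy for
    {IV, IX}, the C copy for {II, XI}.  Labels are mutually exclusive;
    the joint (dominant down, nondominant up) cell gets its own label
    because figure-style mechanism sums count it under both mechanisms.
    """
    if category not in ELD_CATEGORIES:
        raise InvalidInputError(
            f"mechanism defined only for ELD categories, got {category!r}"
        )
    dom, nondom = (
        (change_A, change_C) if category in ("IV", "IX") else (change_C, change_A)
    )
    if dom == "unchanged" and nondom == "unchanged":
        return "none"
    if category in ("IV", "II"):  # higher-expression parent matched
        if dom == "down" and nondom == "up":
            return "dominant_down_nondominant_up"
        if dom == "down":
            return "dominant_down"
        if dom == "unchanged" and nondom == "up":
            return "nondominant_up"
        return "other"
    # lower-expression parent matched
    if dom == "down" and nondom == "down":
        return "both_down"
    if dom == "unchanged" and nondom == "down":
        return "nondominant_down"
    return "other"


@dataclass
class PairExpression:
    """Replicate-level expression of one homoeolog pair (FPKM scale)."""

    pair_id: str
    A_r: np.ndarray
    C_o: np.ndarray
    A_n: np.ndarray
    C_n: np.ndarray

    def __post_init__(self):
        for name in ("A_r", "C_o", "A_n", "C_n"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size < 2:
                raise InvalidInputError(
                    f"{name} of pair {self.pair_id} needs >= 2 replicates"
                )
            setattr(self, name, v)
        if self.A_n.size != self.C_n.size:
            raise InvalidInputError(
                f"pair {self.pair_id}: polyploid homoeologs must share replicates"
            )

    @property
    def S(self) -> np.ndarray:
        """Per-replicate pair total A_n + C_n (recomputed, never cached)."""
        return self.A_n + self.C_n


@dataclass(frozen=True)
class BiasResult:
    pair_id: str
    parent_state: str
    progeny_state: str
    transition: str
    p_parent: float
    p_progeny: float


@dataclass(frozen=True)
class EldResult:
    pair_id: str
    t_SA: TestOutcome
    t_SC: TestOutcome
    t_AC: TestOutcome
    category: str
    group: str
    eld_direction: str
    consistent: bool


@dataclass(frozen=True)
class ExplainResult:
    pair_id: str
    change_A: str
    change_C: str
    mechanism: str
    p_A: float
    p_C: float


def classify_bias(pair: PairExpression, alpha: float = DEFAULT_ALPHA) -> BiasResult:
    """Homoeolog bias states in parents and progeny, and the transition."""
    t_par = t_test(pair.A_r, pair.C_o, alpha=alpha)
    t_pro = t_test(pair.A_n, pair.C_n, alpha=alpha)
    parent_state = _BIAS_STATE[_dir_code(t_par.direction)]
    progeny_state = _BIAS_STATE[_dir_code(t_pro.direction)]
    return BiasResult(
        pair.pair_id,
        parent_state,
        progeny_state,
        transition_of(parent_state, progeny_state),
        t_par.p,
        t_pro.p,
    )


def classify_eld(pair: PairExpression, alpha: float = DEFAULT_ALPHA) -> EldResult:
    """Twelve-category classification of the pair total vs both parents."""
    S = pair.S
    t_SA = t_test(S, pair.A_r, alpha=alpha)
    t_SC = t_test(S, pair.C_o, alpha=alpha)
    t_AC = t_test(pair.A_r, pair.C_o, alpha=alpha)
    d1, d2, d_ac = (_dir_code(t.direction) for t in (t_SA, t_SC, t_AC))
    category = decide_category(d1, d2, d_ac)
    consistent = _EXPECTED_DAC.get(category, d_ac) == d_ac
    return EldResult(
        pair.pair_id,
        t_SA,
        t_SC,
        t_AC,
        category,
        GROUP_OF_CATEGORY[category],
        ELD_DIRECTION_OF_CATEGORY.get(category, "n/a"),
        consistent,
    )


def explain_eld(
    pair: PairExpression, eld: EldResult, alpha: float = DEFAULT_ALPHA
) -> ExplainResult:
    """Individual homoeolog changes (A_n vs A_r, C_n vs C_o) behind an ELD call."""
    if eld.group not in ("ELD_A", "ELD_C"):
        raise InvalidInputError(
            f"pair {pair.pair_id}: explanation defined only for ELD pairs, "
            f"got group {eld.group!r}"
        )
    t_A = t_test(pair.A_n, pair.A_r, alpha=alpha)
    t_C = t_test(pair.C_n, pair.C_o, alpha=alpha)
    change_A = _CHANGE[_dir_code(t_A.direction)]
    change_C = _CHANGE[_dir_code(t_C.direction)]
    return ExplainResult(
        pair.pair_id,
        change_A,
        change_C,
        mechanism_of(eld.category, change_A, change_C),
        t_A.p,
        t_C.p,
    )


def _dir_code(direction: Direction) -> int:
    return {"LT": -1, "EQ": 0, "GT": 1}[direction.value]


def _cmp_exact(a: float, b: float) -> int:
    if np.isclose(a, b, rtol=REL_TOL, atol=0.0):
        return 0
    return 1 if a > b else -1


@dataclass(frozen=True)
class TruthLabels:
    """Noise-free classification of a template's exact means."""

    category: str
    group: str
    eld_direction: str
    parent_state: str
    progeny_state: str
    transition: str
    change_A: str
    change_C: str
    mechanism: str


def truth_label(mu_Ar: float, mu_Co: float, mu_An: float, mu_Cn: float) -> TruthLabels:
    """Exact-mean oracle: same decision tables, equality instead of t-tests.

    EQ means equal to relative tolerance 1e-9; GT/LT by sign.  Applied to
    noise-free data the statistical pipeline reproduces these labels
    exactly (the degenerate-variance t-test convention uses the same
    comparison).
    """
    for name, v in (("mu_Ar", mu_Ar), ("mu_Co", mu_Co), ("mu_An", mu_An), ("mu_Cn", mu_Cn)):
        if v < 0:
            raise InvalidInputError(f"{name} must be >= 0, got {v}")
    S = mu_An + mu_Cn
    d1 = _cmp_exact(S, mu_Ar)
    d2 = _cmp_exact(S, mu_Co)
    d_ac = _cmp_exact(mu_Ar, mu_Co)
    category = decide_category(d1, d2, d_ac)
    group = GROUP_OF_CATEGORY[category]
    parent_state = _BIAS_STATE[d_ac]
    progeny_state = _BIAS_STATE[_cmp_exact(mu_An, mu_Cn)]
    change_A = _CHANGE[_cmp_exact(mu_An, mu_Ar)]
    change_C = _CHANGE[_cmp_exact(mu_Cn, mu_Co)]
    mechanism = (
        mechanism_of(category, change_A, change_C)
        if category in ELD_CATEGORIES
        else "n/a"
    )
    return TruthLabels(
        category,
        group,
        ELD_DIRECTION_OF_CATEGORY.get(category, "n/a"),
        parent_state,
        progeny_state,
        transition_of(parent_state, progeny_state),
        change_A,
        change_C,
        mechanism,
    )


# ---------------------------------------------------------------------------
# dataset-level (vectorized) classification


@dataclass
class PairDataset:
    """Matrices of replicate values for many pairs (rows align on pair_id)."""

    pair_id: np.ndarray
    A_r: np.ndarray
    C_o: np.ndarray
    A_n: np.ndarray
    C_n: np.ndarray

    def __post_init__(self):
        n = len(self.pair_id)
        for name in ("A_r", "C_o", "A_n", "C_n"):
            m = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if m.shape[0] != n:
                raise InvalidInputError(f"{name} has {m.shape[0]} rows, expected {n}")
            if m.shape[1] < 2:
                raise InvalidInputError(f"{name} needs >= 2 replicate columns")
            setattr(self, name, m)
        if self.A_n.shape[1] != self.C_n.shape[1]:
            raise InvalidInputError("polyploid homoeolog matrices must share replicates")

    @classmethod
    def from_tables(cls, pair_map: pd.DataFrame, parent_a, parent_c, polyploid):
        """Assemble matrices from expression tables and a pair map.

        ``parent_a``/``parent_c``/``polyploid`` are ExpressionTable objects
        (see :mod:`homeobias.io`); the polyploid table holds both subgenomes.
        """
        missing = []
        for col, table in (("gene_id_A", parent_a), ("gene_id_C", parent_c)):
            absent = set(pair_map[col]) - set(table.data.index)
            missing.extend(sorted(absent))
        absent_poly = (
            set(pair_map["gene_id_A"]) | set(pair_map["gene_id_C"])
        ) - set(polyploid.data.index)
        missing.extend(sorted(absent_poly))
        if missing:
            raise LookupMismatchError(
                f"pair genes missing from expression tables: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        return cls(
            pair_id=pair_map["pair_id"].to_numpy(),
            A_r=parent_a.data.loc[pair_map["gene_id_A"]].to_numpy(),
            C_o=parent_c.data.loc[pair_map["gene_id_C"]].to_numpy(),
            A_n=polyploid.data.loc[pair_map["gene_id_A"]].to_numpy(),
            C_n=polyploid.data.loc[pair_map["gene_id_C"]].to_numpy(),
        )

    @property
    def S(self) -> np.ndarray:
        return self.A_n + self.C_n

    def __len__(self) -> int:
        return len(self.pair_id)

    def pair(self, i: int) -> PairExpression:
        return PairExpression(
            str(self.pair_id[i]), self.A_r[i], self.C_o[i], self.A_n[i], self.C_n[i]
        )

    def swapped(self) -> "PairDataset":
        """A/C relabeling (A_r<->C_o, A_n<->C_n) for symmetry checks."""
        return PairDataset(self.pair_id, self.C_o, self.A_r, self.C_n, self.A_n)


def classify_bias_table(ds: PairDataset, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    p_par, d_par, _, _ = t_test_many(ds.A_r, ds.C_o, alpha=alpha)
    p_pro, d_pro, _, _ = t_test_many(ds.A_n, ds.C_n, alpha=alpha)
    parent_state = [_BIAS_STATE[int(d)] for d in d_par]
    progeny_state = [_BIAS_STATE[int(d)] for d in d_pro]
    return pd.DataFrame(
        {
            "pair_id": ds.pair_id,
            "parent_state": parent_state,
            "progeny_state": progeny_state,
            "transition": [
                transition_of(a, b) for a, b in zip(parent_state, progeny_state)
            ],
            "p_parent": p_par,
            "p_progeny": p_pro,
        }
    )


def classify_eld_table(ds: PairDataset, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    S = ds.S
    p_sa, d1, _, _ = t_test_many(S, ds.A_r, alpha=alpha)
    p_sc, d2, _, _ = t_test_many(S, ds.C_o, alpha=alpha)
    p_ac, d_ac, _, _ = t_test_many(ds.A_r, ds.C_o, alpha=alpha)
    categories = [
        decide_category(int(a), int(b), int(c)) for a, b, c in zip(d1, d2, d_ac)
    ]
    return pd.DataFrame(
        {
            "pair_id": ds.pair_id,
            "category": categories,
            "group": [GROUP_OF_CATEGORY[c] for c in categories],
            "eld_direction": [
                ELD_DIRECTION_OF_CATEGORY.get(c, "n/a") for c in categories
            ],
            "p_SA": p_sa,
            "p_SC": p_sc,
            "p_AC": p_ac,
            "consistent": [
                _EXPECTED_DAC.get(c, int(d)) == int(d)
                for c, d in zip(categories, d_ac)
            ],
        }
    )


def explain_eld_table(
    ds: PairDataset, eld: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Explanation decomposition for every ELD-group pair in ``eld``."""
    eld_mask = eld["group"].isin(["ELD_A", "ELD_C"]).to_numpy()
    idx = np.flatnonzero(eld_mask)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["pair_id", "category", "change_A", "change_C", "mechanism", "p_A", "p_C"]
        )
    p_a, d_a, _, _ = t_test_many(ds.A_n[idx], ds.A_r[idx], alpha=alpha)
    p_c, d_c, _, _ = t_test_many(ds.C_n[idx], ds.C_o[idx], alpha=alpha)
    change_A = [_CHANGE[int(d)] for d in d_a]
    change_C = [_CHANGE[int(d)] for d in d_c]
    categories = eld["category"].to_numpy()[idx]
    return pd.DataFrame(
        {
            "pair_id": np.asarray(ds.pair_id)[idx],
            "category": categories,
            "change_A": change_A,
            "change_C": change_C,
            "mechanism": [
                mechanism_of(cat, a, c)
                for cat, a, c in zip(categories, change_A, change_C)
            ],
            "p_A": p_a,
            "p_C": p_c,
        }
    )
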