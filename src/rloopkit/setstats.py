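"""Fisher-exact enrichment between two id sets over a fixed universe."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable", "build_table", "fisher_enrichment", "enrichment_report"]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # in both sets
    b: int  # set1 only
    c: int  # set2 only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


def build_table(set1, set2, universe) -> ContingencyTable:
    """Counts (both, set1-only, set2-only, neither) over the universe.

    Ids outside the universe are dropped with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    s1, s2 = set(set1), set(set2)
    for name, s in (("set1", s1), ("set2", s2)):
        extra = s - uni
        if extra:
            warnings.warn(f"{len(extra)} member(s) of {name} absent from universe; dropped")
    s1 &= uni
    s2 &= uni
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    return ContingencyTable(a, b, c, len(uni) - a - b - c)


def fisher_enrichment(t: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher exact p-value for overlap enrichment.

    ``greater`` sums the hypergeometric upper tail P(X >= a) in log space
    (finite for universes up to ~1e6); ``two_sided`` sums all tables at
    most as probable as the observed one.
    """
    if alternative == "greater":
        # X ~ Hypergeom(N, K=|set1|, n=|set2|); P(X >= a) = sf(a - 1)
        return float(stats.hypergeom.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c))
    if alternative == "two_sided":
        return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                        alternative="two-sided")[1])
    raise ValueError(f"unknown alternative {alternative!r}")


def enrichment_report(set1, set2, universe, alternative: str = "greater") -> pd.DataFrame:
    t = build_table(set1, set2, universe)
    p = fisher_enrichment(t, alternative)
    return pd.DataFrame([{
        "a_both": t.a, "b_set1_only": t.b, "c_set2_only": t.c, "d_neither": t.d,
        "universe": t.n, "odds_ratio": t.odds_ratio,
        "alternative": alternative, "p_value": p,
    }])
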