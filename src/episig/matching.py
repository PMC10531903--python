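"""Matched-control selection: exact on sex and array type, nearest
neighbor on age, at a fixed case:control ratio (default 1:5), without
replacement.

Cases are processed scarcity-first (fewest compatible pool controls
first) so an easy case cannot starve a hard one; within a case,
candidates are taken in (|age gap|, sample_id) order, which makes the
selected set invariant to pool row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class MatchingError(RuntimeError):
    """A case could not be supplied with enough compatible controls."""


@dataclass
class MatchResult:
    assignment: dict[str, list[str]]
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def matched_control_ids(self) -> list[str]:
        out: list[str] = []
        for case in sorted(self.assignment):
            out.extend(self.assignment[case])
        return out


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 5,
) -> MatchResult:
    """Select ``ratio`` controls per case from ``pool``.

    Both frames need columns ``sample_id, age, sex, array_type``.  Raises
    :class:`MatchingError` naming the first starved case when the pool
    cannot supply enough exact sex/array matches.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    for frame, name in ((cases, "cases"), (pool, "pool")):
        missing = {"sample_id", "age", "sex", "array_type"} - set(frame.columns)
        if missing:
            raise ValueError(f"{name} sheet missing columns {sorted(missing)}")

    pool = pool.sort_values("sample_id").reset_index(drop=True)
    compatible: dict[str, pd.DataFrame] = {}
    for _, case in cases.iterrows():
        cand = pool[(pool["sex"] == case["sex"])
                    & (pool["array_type"] == case["array_type"])]
        compatible[case["sample_id"]] = cand

    # scarcity-first order, sample_id as deterministic tie-break
    order = sorted(cases["sample_id"],
                   key=lambda c: (len(compatible[c]), c))
    used: set[str] = set()
    assignment: dict[str, list[str]] = {}
    diag_rows = []
    case_age = cases.set_index("sample_id")["age"]
    for case_id in order:
        cand = compatible[case_id]
        cand = cand[~cand["sample_id"].isin(used)]
        if len(cand) < ratio:
            raise MatchingError(
                f"case {case_id!r}: only {len(cand)} compatible controls "
                f"remain in the pool, need {ratio}")
        gaps = (cand["age"] - case_age[case_id]).abs()
        picked = (
            pd.DataFrame({"sample_id": cand["sample_id"], "gap": gaps})
            .sort_values(["gap", "sample_id"], kind="mergesort")
            .head(ratio)
        )
        assignment[case_id] = picked["sample_id"].tolist()
        used.update(assignment[case_id])
        diag_rows.append({"case_id": case_id,
                          "mean_age_gap": float(picked["gap"].mean())})

    return MatchResult(
        assignment=assignment,
        diagnostics=pd.DataFrame(diag_rows).set_index("case_id"),
    )
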