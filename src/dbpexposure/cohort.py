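"""Eligibility cascade and analysis-dataset assembly.

The analysis population is carved out of the raw birth records by a fixed,
ordered sequence of exclusions: singleton births only; one pregnancy per
mother (chosen at random with a fixed seed when a mother appears more than
once); water-use questionnaire present; THM exposure computable for every
trimester; birth weight recorded; term delivery (>= 37 completed weeks).
The cascade order matters and is applied exactly as listed, with a log of
counts at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TERM_WEEKS = 37

#: columns apply_exclusions needs; flags are precomputed upstream
REQUIRED_COLUMNS = (
    "mother_id", "pregnancy_id", "singleton", "has_water_use",
    "thm_complete", "birth_weight_g", "gestational_age_wk",
)


@dataclass
class CascadeLog:
    """Ordered record of (stage, n excluded, n remaining)."""

    n_input: int
    stages: list = field(default_factory=list)

    def add(self, label: str, n_excluded: int, n_remaining: int) -> None:
        if self.stages and n_remaining > self.stages[-1][2]:
            raise ValueError("cascade counts must be non-increasing")
        self.stages.append((label, int(n_excluded), int(n_remaining)))

    @property
    def n_final(self) -> int:
        return self.stages[-1][2] if self.stages else self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "n_excluded", "n_remaining"])

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stages": [
                {"stage": s, "n_excluded": e, "n_remaining": r}
                for s, e, r in self.stages
            ],
            "n_final": self.n_final,
        }

    def __str__(self) -> str:
        lines = [f"input records: {self.n_input}"]
        for s, e, r in self.stages:
            lines.append(f"  {s}: excluded {e}, remaining {r}")
        return "\n".join(lines)


def apply_exclusions(records: pd.DataFrame, seed: int
                     ) -> tuple[pd.DataFrame, CascadeLog]:
    """Apply the eligibility cascade in its fixed order.

    The repeated-pregnancy stage keeps one uniformly chosen pregnancy per
    mother; with the same seed the choice (and hence the whole cascade) is
    bit-identical across runs.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    log = CascadeLog(n_input=len(records))
    df = records

    kept = df[df["singleton"].astype(bool)]
    log.add("singleton births", len(df) - len(kept), len(kept))
    df = kept

    # one pregnancy per mother, seeded uniform choice in a stable order
    rng = np.random.default_rng(seed)
    order = df.sort_values(["mother_id", "pregnancy_id"], kind="mergesort")
    keep_idx = []
    for _, grp in order.groupby("mother_id", sort=True):
        if len(grp) == 1:
            keep_idx.append(grp.index[0])
        else:
            keep_idx.append(grp.index[rng.integers(len(grp))])
    kept = df.loc[df.index.isin(keep_idx)]
    log.add("one pregnancy per mother", len(df) - len(kept), len(kept))
    df = kept

    kept = df[df["has_water_use"].astype(bool)]
    log.add("water-use data present", len(df) - len(kept), len(kept))
    df = kept

    kept = df[df["thm_complete"].astype(bool)]
    log.add("THM exposure computable for all trimesters",
            len(df) - len(kept), len(kept))
    df = kept

    kept = df[df["birth_weight_g"].notna()]
    log.add("birth weight recorded", len(df) - len(kept), len(kept))
    df = kept

    kept = df[df["gestational_age_wk"] >= TERM_WEEKS]
    log.add("term birth (>= 37 weeks)", len(df) - len(kept), len(kept))
    df = kept

    return df.copy(), log


def complete_case(records: pd.DataFrame, covariates: list[str]
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Drop records missing any listed covariate (complete-case analysis).

    Returns the retained records and the per-covariate missingness count
    on the input.
    """
    unknown = [c for c in covariates if c not in records.columns]
    if unknown:
        raise ValueError(f"unknown covariate name(s): {unknown}")
    missingness = records[covariates].isna().sum()
    kept = records.dropna(subset=covariates)
    return kept.copy(), missingness
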