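"""Fitness scoring and hit calling for pooled selections.

The fitness (enrichment) score of a cassette is the log2-fold change of its
relative frequency between the pre- and post-selection samples,

    score = log2( ((c_post + a) / T_post) / ((c_pre + a) / T_pre) ),

with pseudocount a (default 0.5) guarding zero counts. Synonymous-control
cassettes change the DNA but not the protein, so their scores form an
empirical null for wild-type fitness; a variant is called a hit when its
score exceeds the control mean + k standard deviations (k = 2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readproc import CountTable

FITNESS_COLUMNS = [
    "cassette_id", "gene", "residue", "wt_aa", "mut_aa", "is_control",
    "condition", "fitness_score",
]

HIT = "hit"
NO_HIT = "no-hit"
NOT_ASSAYED = "not-assayed"


def log2_enrichment(
    count_pre, total_pre, count_post, total_post, pseudocount: float = 0.5
):
    """Log2-fold frequency enrichment between pre and post samples.

    Accepts scalars or arrays. With pseudocount 0 a zero count makes the
    score undefined; it is returned as NaN with a warning.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(np.asarray(total_pre) <= 0) or np.any(np.asarray(total_post) <= 0):
        raise ValueError("totals must be positive")
    c_pre = np.asarray(count_pre, dtype=float) + pseudocount
    c_post = np.asarray(count_post, dtype=float) + pseudocount
    undefined = (c_pre == 0) | (c_post == 0)
    if np.any(undefined):
        warnings.warn(
            "zero count with pseudocount 0: enrichment undefined, reported as NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2((c_post / total_post) / (c_pre / total_pre))
    score = np.where(undefined, np.nan, score)
    return float(score) if np.isscalar(count_pre) else score


def build_fitness_table(
    count_table: CountTable,
    design: pd.DataFrame,
    condition: str,
    sample_pre: str = "pre",
    sample_post: str = "post",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Score every designed cassette for one condition.

    `design` is the design TSV frame (cassette_id, gene, position, wt_aa,
    mut_aa, is_control, ...). Frequencies are taken over mapped reads.
    """
    pre = count_table.counts_for(sample_pre)
    post = count_table.counts_for(sample_post)
    t_pre = count_table.mapped_total(sample_pre)
    t_post = count_table.mapped_total(sample_post)
    rows = []
    for _, d in design.iterrows():
        cid = d["cassette_id"]
        score = log2_enrichment(
            int(pre.get(cid, 0)), t_pre, int(post.get(cid, 0)), t_post, pseudocount
        )
        rows.append(
            {
                "cassette_id": cid,
                "gene": d["gene"],
                "residue": int(d["position"]),
                "wt_aa": d["wt_aa"],
                "mut_aa": d["mut_aa"],
                "is_control": bool(d["is_control"]),
                "condition": condition,
                "fitness_score": score,
            }
        )
    return pd.DataFrame(rows, columns=FITNESS_COLUMNS)


@dataclass(frozen=True)
class NullModel:
    """Synonymous-control null: mean, SD and the derived hit cutoff."""

    condition: str
    mean: float
    sd: float
    k: float
    n_controls: int

    @property
    def cutoff(self) -> float:
        return self.mean + self.k * self.sd

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition": self.condition,
                    "mean": self.mean,
                    "sd": self.sd,
                    "k": self.k,
                    "cutoff": self.cutoff,
                    "n_controls": self.n_controls,
                },
                fh,
                indent=2,
            )


def synonymous_null(
    fitness_table: pd.DataFrame, condition: str, k: float = 2.0
) -> NullModel:
    """Estimate the wild-type fitness null from synonymous controls.

    Sample (n-1) standard deviation; at least two finite control scores are
    required.
    """
    sub = fitness_table[
        (fitness_table["condition"] == condition) & fitness_table["is_control"]
    ]
    values = sub["fitness_score"].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError(
            f"condition {condition!r}: {len(values)} finite control scores; "
            "need >= 2 to estimate the null"
        )
    return NullModel(
        condition=condition,
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        k=k,
        n_controls=len(values),
    )


def call_hits(
    fitness_table: pd.DataFrame, null_models: dict[str, NullModel]
) -> pd.DataFrame:
    """Flag variants scoring strictly above each condition's null cutoff.

    Controls are never reported as hits. Conditions without a null model get
    status not-assayed with a warning. Output is sorted by descending score
    within condition.
    """
    out = fitness_table.copy()
    statuses = []
    for _, row in out.iterrows():
        null = null_models.get(row["condition"])
        if null is None:
            statuses.append(NOT_ASSAYED)
            continue
        if row["is_control"]:
            statuses.append(NO_HIT)
        elif np.isfinite(row["fitness_score"]) and row["fitness_score"] > null.cutoff:
            statuses.append(HIT)
        else:
            statuses.append(NO_HIT)
    missing = {c for c in out["condition"].unique() if c not in null_models}
    if missing:
        warnings.warn(f"no null model for conditions {sorted(missing)}; not assayed")
    out["status"] = statuses
    return out.sort_values(
        ["condition", "fitness_score"], ascending=[True, False]
    ).reset_index(drop=True)


def empirical_fdr(
    fitness_table: pd.DataFrame, null: NullModel
) -> tuple[int, float]:
    """Controls above the cutoff: a sanity report that never alters calls."""
    sub = fitness_table[
        (fitness_table["condition"] == null.condition) & fitness_table["is_control"]
    ]
    values = sub["fitness_score"].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    n_above = int(np.sum(values > null.cutoff))
    return n_above, n_above / len(values) if len(values) else float("nan")


def _variant_label(row) -> str:
    return f"{row['gene']} {row['wt_aa']}{row['residue']}{row['mut_aa']}"


def pleiotropy_matrix(
    hit_tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-condition summary of non-control variants.

    Returns (matrix, shared_hits): `matrix` has one row per variant and one
    status column per condition (hit / no-hit / not-assayed) plus score
    columns; `shared_hits` lists variants hit in two or more conditions.
    """
    if isinstance(hit_tables, dict):
        tables = list(hit_tables.values())
    else:
        tables = list(hit_tables)
    if not tables:
        raise ValueError("at least one condition required")
    combined = pd.concat(tables, ignore_index=True)
    combined = combined[~combined["is_control"]].copy()
    combined["variant"] = combined.apply(_variant_label, axis=1)
    conditions = sorted(combined["condition"].unique())
    status = combined.pivot_table(
        index="variant", columns="condition", values="status", aggfunc="first"
    ).reindex(columns=conditions)
    scores = combined.pivot_table(
        index="variant", columns="condition", values="fitness_score", aggfunc="first"
    ).reindex(columns=conditions)
    status = status.fillna(NOT_ASSAYED)
    matrix = pd.concat(
        {"status": status, "fitness_score": scores}, axis=1
    ).sort_index()
    hit_mask = status == HIT
    shared = [
        {
            "variant": variant,
            "conditions": ",".join(c for c in conditions if hit_mask.loc[variant, c]),
            "n_conditions": int(hit_mask.loc[variant].sum()),
        }
        for variant in status.index
        if hit_mask.loc[variant].sum() >= 2
    ]
    shared_df = pd.DataFrame(shared, columns=["variant", "conditions", "n_conditions"])
    return matrix, shared_df
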