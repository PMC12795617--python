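"""Report-table rendering: model ladders and coefficient summaries.

Tables use the conventional quasi-likelihood selection layout — model label,
K (#parameters), QAICc, dQAICc, QAICc weight, cumulative weight,
quasi-log-likelihood — rounded half-up to two decimals.
"""

from __future__ import annotations

import io
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .selection import ModelLadder

LADDER_COLUMNS = (
    "model",
    "K",
    "QAICc",
    "dQAICc",
    "weight",
    "cum_weight",
    "quasi_loglik",
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (0.125 -> 0.13), the convention used
    in the report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def render_ladder(lad: ModelLadder, decimals: int = 2) -> str:
    """Render a ladder as a delimited text table (tab-separated)."""
    df = lad.table.copy()
    for col in ("QAICc", "dQAICc", "weight", "cum_weight", "quasi_loglik"):
        df[col] = df[col].map(lambda v: f"{round_half_up(v, decimals):.{decimals}f}")
    lines = ["\t".join(LADDER_COLUMNS)]
    for _, row in df.iterrows():
        lines.append("\t".join(str(row[c]) for c in LADDER_COLUMNS))
    if not (lad.table["dQAICc"] <= lad.delta_retain).any():
        lines.append(f"# no models within dQAICc <= {lad.delta_retain}")
    return "\n".join(lines) + "\n"


def parse_ladder(text: str) -> pd.DataFrame:
    """Parse a rendered ladder back into a DataFrame (2-decimal precision)."""
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def beta_summary(lad: ModelLadder, decimals: int = 2) -> pd.DataFrame:
    """Coefficient summary in 'estimate (SE)' style.

    The null-model intercept comes from the intercept-only occupancy row;
    each covariate's estimate is taken from the top-ranked model in which
    it first appears.
    """
    rows = []
    fits = [lad.fits[lbl] for lbl in lad.table["model"]]
    null = next(
        (f for f in fits if not f.spec.psi_covariates), None
    )
    if null is not None:
        rows.append(
            (
                "Null",
                f"{round_half_up(float(null.beta_psi['(Intercept)']), decimals):.{decimals}f}"
                f" ({round_half_up(float(null.se_psi['(Intercept)']), decimals):.{decimals}f})",
                null.spec.label(),
            )
        )
    seen: set[str] = set()
    for f in fits:  # already in rank order
        for c in f.spec.psi_covariates:
            if c in seen:
                continue
            seen.add(c)
            rows.append(
                (
                    c,
                    f"{round_half_up(float(f.beta_psi[c]), decimals):.{decimals}f}"
                    f" ({round_half_up(float(f.se_psi[c]), decimals):.{decimals}f})",
                    f.spec.label(),
                )
            )
    return pd.DataFrame(rows, columns=["covariate", "estimate (SE)", "from model"])
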