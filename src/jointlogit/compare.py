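"""Separate-vs-simultaneous coefficient comparison table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ComparabilityError

#: Labels for the three outcomes of the emulated survey, in pattern order.
OUTCOME_LABELS = {1: "blood_test", 2: "aware_hiv_aids", 3: "aware_campaign"}


@dataclass
class ComparisonTable:
    """Per term x outcome: coefficient and p-value under both models, plus a
    discordance flag where the significance classification (at alpha)
    differs between the separate and the joint fit."""

    rows: pd.DataFrame
    alpha: float
    flagged: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        out = self.rows.copy()
        for col in ("separate_coeff", "joint_coeff"):
            out[col] = out[col].round(3)
        for col in ("separate_p", "joint_p"):
            out[col] = out[col].round(4)
        out.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [
            f"{'outcome':<16}{'term':<22}{'sep coeff':>10}{'sep p':>9}"
            f"{'joint coeff':>12}{'joint p':>9}  flag"
        ]
        for _, r in self.rows.iterrows():
            lines.append(
                f"{r['outcome']:<16}{r['term']:<22}{r['separate_coeff']:>10.3f}"
                f"{r['separate_p']:>9.4f}{r['joint_coeff']:>12.3f}"
                f"{r['joint_p']:>9.4f}  {'*' if r['discordant'] else ''}"
            )
        return "\n".join(lines)


def _p_from(est: float, se) -> float:
    if se is None or not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2.0 * norm.sf(abs(est / se)))


def compare_fits(separate_fits, joint_fit, alpha: float = 0.05) -> ComparisonTable:
    """Align the three separate fits with the joint fit term by term.

    Raises :class:`ComparabilityError` when the fits were made on different
    analysis sets or their term names disagree.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if len(separate_fits) != 3:
        raise ComparabilityError("expected exactly 3 separate fits")
    joint_terms = list(joint_fit.term_names)
    rows = []
    flagged = []
    for fit in sorted(separate_fits, key=lambda f: f.outcome):
        if list(fit.term_names) != joint_terms:
            offenders = sorted(
                set(fit.term_names).symmetric_difference(joint_terms)
            )
            raise ComparabilityError(
                f"term names of separate fit (outcome {fit.outcome}) do not "
                f"match the joint fit: {offenders}"
            )
        if fit.data_hash and joint_fit.data_hash and fit.data_hash != joint_fit.data_hash:
            raise ComparabilityError(
                "separate and joint fits were not produced on the same analysis set"
            )
        q = fit.outcome
        label = OUTCOME_LABELS.get(q, f"outcome{q}")
        for i, term in enumerate(joint_terms):
            sep_coeff = float(fit.beta[i])
            sep_p = _p_from(
                sep_coeff, None if fit.se_beta is None else fit.se_beta[i]
            )
            joint_coeff = float(joint_fit.beta[q - 1, i])
            joint_p = _p_from(
                joint_coeff,
                None if joint_fit.se_beta is None else joint_fit.se_beta[q - 1, i],
            )
            sig_sep = np.isfinite(sep_p) and sep_p < alpha
            sig_joint = np.isfinite(joint_p) and joint_p < alpha
            discordant = bool(sig_sep != sig_joint) and alpha < 1.0
            rows.append(
                {
                    "outcome": label,
                    "term": term,
                    "separate_coeff": sep_coeff,
                    "separate_p": sep_p,
                    "joint_coeff": joint_coeff,
                    "joint_p": joint_p,
                    "discordant": discordant,
                }
            )
            if discordant:
                flagged.append((label, term))
    return ComparisonTable(rows=pd.DataFrame(rows), alpha=alpha, flagged=flagged)
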