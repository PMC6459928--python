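"""Mutational-signature deconvolution and downstream summaries.

A sample's 96-channel substitution spectrum is decomposed against a
30-signature catalog by non-negative least squares:

    x* = argmin_{x >= 0} || C x - s ||_2

where C is the 96x30 catalog (columns sum to 1) and s the observed
spectrum.  Contributions are reported both on the raw (mutation
count) scale and as proportions; the dominant signature is the
argmax proportion (ties broken toward the lowest signature index).

Trunk-vs-branch dynamics split each patient's mutations by their
phylogenetic timing, fit exposures per phase, and compare a chosen
signature's contribution across patients with a two-sided paired
t-test.  The signature-3 / BRCA1-2 association is quantified by the
Mann-Whitney AUC of signature-3 proportion against the deficiency
label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .catalog import CHANNELS_96, channel_of
from .records import MutationRecord, VariantType

log = logging.getLogger(__name__)

#: minimum SNVs for a confidently interpretable exposure fit
LOW_CONFIDENCE_SNVS = 20


def build_spectrum(snvs: list[MutationRecord]) -> np.ndarray:
    """Count SNVs into the 96 pyrimidine-standardized channels.

    Records without a context, non-SNVs, and malformed contexts are
    skipped with a log message; the returned vector sums to the number
    of contributing SNVs.
    """
    spectrum = np.zeros(96)
    for rec in snvs:
        if rec.variant_type != VariantType.SNV or rec.tri_context is None:
            continue
        try:
            spectrum[channel_of(rec.ref, rec.alt, rec.tri_context)] += 1
        except ValueError as exc:
            log.warning("skipping %s: %s", rec.mutation_id, exc)
    return spectrum


@dataclass
class SignatureExposure:
    """Per-sample (or per-phase) signature contribution vector."""

    sample_id: str
    contributions: np.ndarray
    reconstruction_error: float
    n_snvs: int
    low_confidence: bool = False
    signature_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def proportions(self) -> np.ndarray:
        total = self.contributions.sum()
        if total == 0:
            return np.zeros_like(self.contributions)
        return self.contributions / total

    @property
    def dominant(self) -> int | None:
        """0-based index of the dominant signature; None for a zero fit.

        Ties resolve to the lowest signature index (np.argmax).
        """
        if self.contributions.sum() == 0:
            return None
        return int(np.argmax(self.proportions))


def fit_exposures(
    spectrum: np.ndarray,
    catalog: pd.DataFrame,
    sample_id: str = "",
) -> SignatureExposure:
    """Non-negative least-squares deconvolution of one spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (96,):
        raise ValueError("spectrum must have 96 channels")
    if spectrum.sum() == 0:
        return SignatureExposure(
            sample_id, np.zeros(catalog.shape[1]), 0.0, 0,
            signature_names=tuple(catalog.columns),
        )
    coefs, resid = scipy.optimize.nnls(catalog.to_numpy(), spectrum)
    n = int(round(spectrum.sum()))
    return SignatureExposure(
        sample_id, coefs, float(resid), n,
        low_confidence=n < LOW_CONFIDENCE_SNVS,
        signature_names=tuple(catalog.columns),
    )


@dataclass
class PhaseComparison:
    """Cohort-level early-vs-late contrast of one signature."""

    signature: int
    trunk_values: np.ndarray
    branch_values: np.ndarray
    t_statistic: float
    p_value: float
    n_patients: int


def phase_exposures(
    mutations: list[MutationRecord],
    timing_labels: dict[str, str],
    catalog: pd.DataFrame,
    patient_id: str = "",
) -> tuple[SignatureExposure, SignatureExposure | None]:
    """Fit separate exposures for trunk (early) and branch (late) SNVs.

    ``timing_labels`` maps mutation_id to ``trunk``/``shared``/``private``;
    shared and private mutations together form the branch (late) phase.
    Returns (trunk exposure, branch exposure); the branch exposure is
    None when the patient has no branch SNVs.
    """
    trunk = [m for m in mutations if timing_labels.get(m.mutation_id) == "trunk"]
    branch = [
        m for m in mutations
        if timing_labels.get(m.mutation_id) in ("shared", "private")
    ]
    trunk_exp = fit_exposures(build_spectrum(trunk), catalog, f"{patient_id}:trunk")
    branch_spec = build_spectrum(branch)
    if branch_spec.sum() == 0:
        return trunk_exp, None
    return trunk_exp, fit_exposures(branch_spec, catalog, f"{patient_id}:branch")


def compare_phases(
    pairs: list[tuple[SignatureExposure, SignatureExposure | None]],
    signature: int,
) -> PhaseComparison:
    """Paired two-sided t-test of one signature's proportion, trunk vs branch.

    ``signature`` is the 0-based catalog column index.  Patients whose
    branch phase is empty are excluded from the test.
    """
    trunk_vals, branch_vals = [], []
    for trunk_exp, branch_exp in pairs:
        if branch_exp is None:
            continue
        trunk_vals.append(trunk_exp.proportions[signature])
        branch_vals.append(branch_exp.proportions[signature])
    trunk_arr, branch_arr = np.asarray(trunk_vals), np.asarray(branch_vals)
    if len(trunk_arr) < 2:
        raise ValueError("paired test needs >= 2 patients with both phases")
    t, p = scipy.stats.ttest_rel(branch_arr, trunk_arr)
    return PhaseComparison(signature, trunk_arr, branch_arr, float(t), float(p),
                           len(trunk_arr))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = U / (n+ * n-), computed from mid-ranks (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auc_signature3(
    sig3_proportions: np.ndarray, labels: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """AUC of signature-3 contribution for BRCA1/2 deficiency, plus ROC points."""
    auc = mann_whitney_auc(sig3_proportions, labels)
    scores = np.asarray(sig3_proportions, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = [(scores[labels] >= t).mean() for t in thresholds]
    fpr = [(scores[~labels] >= t).mean() for t in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, roc
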