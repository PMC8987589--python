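"""96-context mutational spectra and signature refitting.

A sample's SNVs are binned into the 96 trinucleotide substitution
categories (six pyrimidine-strand substitution classes x 16 flanking-base
combinations).  The spectrum is then expressed as a non-negative weighted
combination of known signature profiles by greedy forward selection with
non-negative least squares — the standard refitting strategy: starting
from no signatures, repeatedly add the signature whose inclusion most
reduces the squared reconstruction error, stop when the relative
improvement falls below a tolerance, zero out weights below a cutoff
(6% by default) and renormalise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical ordering of the 96 categories: substitution class, then 5'
#: base, then 3' base — e.g. "A[C>A]A", "A[C>A]C", ...
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class TrinucSpectrum:
    """96 non-negative counts in :data:`CONTEXT_LABELS` order."""

    counts: np.ndarray
    skipped: int = 0  # non-SNV calls not binned

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 bins")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureMatrix:
    names: list[str]
    profiles: np.ndarray  # (96, n_signatures), columns sum to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise ValueError("profiles must be 96 x n_signatures")
        if (self.profiles < 0).any():
            raise ValueError("negative signature probability")
        sums = self.profiles.sum(axis=0)
        if np.abs(sums - 1).max() > 1e-6:
            raise ValueError("each signature profile must sum to 1")


@dataclass
class SignatureExposure:
    weights: dict[str, float]
    unexplained: float  # residual SSE on the normalised spectrum
    n_mutations: int


def bin_index(sub_class: str, five: str, three: str) -> int:
    return _LABEL_INDEX[f"{five}[{sub_class}]{three}"]


def context_bin(ref: str, alt: str, context: str) -> int:
    """96-bin index for one SNV given its reference trinucleotide context.

    Purine-reference SNVs are reverse-complemented onto the pyrimidine
    strand first.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} middle base != ref {ref!r}")
    if ref in ("A", "G"):
        context = revcomp(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return bin_index(f"{ref}>{alt}", context[0], context[2])


def build_spectrum(calls, context_of) -> TrinucSpectrum:
    """Bin a sample's SNVs into the 96-context spectrum.

    ``context_of`` maps VariantKey -> reference 3-mer centred on the
    variant.  Indels are skipped and tallied in ``skipped``; an SNV whose
    context disagrees with its reference allele is an error.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    for c in calls:
        key = c.key
        if not key.is_snv:
            skipped += 1
            continue
        counts[context_bin(key.ref, key.alt, context_of[key])] += 1
    return TrinucSpectrum(counts=counts, skipped=skipped)


def six_class_summary(spec: TrinucSpectrum) -> np.ndarray:
    """Fractions of the six substitution classes (C>A ... T>G), summing to 1."""
    if spec.total == 0:
        raise ValueError("empty spectrum")
    per_class = spec.counts.reshape(6, 16).sum(axis=1)
    return per_class / per_class.sum()


def _nnls_sse(P: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    w, rnorm = nnls(P, target)
    return w, rnorm ** 2


def refit_exposures(spec: TrinucSpectrum, sigs: SignatureMatrix,
                    weight_cutoff: float = 0.06,
                    tol: float = 1e-3) -> SignatureExposure:
    """Refit a spectrum as a non-negative signature combination.

    Greedy forward selection: add, one at a time, the signature whose
    inclusion (all selected weights refit by NNLS on the normalised
    spectrum) most reduces the SSE; stop when the relative SSE improvement
    drops below ``tol``.  Weights below ``weight_cutoff`` are zeroed and
    the rest rescaled to the pre-cutoff total; weights are normalised so
    they never exceed total mass 1.
    """
    if spec.total == 0:
        raise ValueError("cannot refit an empty spectrum")
    target = spec.counts / spec.total
    P = sigs.profiles
    n = len(sigs.names)

    selected: list[int] = []
    sse = float(target @ target)  # SSE of the empty model
    weights = np.zeros(0)
    while len(selected) < n:
        best_j, best_sse, best_w = -1, sse, None
        for j in range(n):
            if j in selected:
                continue
            cols = selected + [j]
            w, cand_sse = _nnls_sse(P[:, cols], target)
            if cand_sse < best_sse:
                best_j, best_sse, best_w = j, cand_sse, w
        if best_j < 0:
            break
        improvement = (sse - best_sse) / sse if sse > 0 else 0.0
        if improvement < tol:
            break
        selected.append(best_j)
        sse, weights = best_sse, best_w

    full = np.zeros(n)
    if selected:
        full[selected] = weights
    total_mass = full.sum()
    if total_mass > 1.0:
        full /= total_mass
        total_mass = 1.0
    kept = full >= weight_cutoff
    if kept.any() and not kept.all():
        pre_cutoff = full.sum()
        full[~kept] = 0.0
        full *= pre_cutoff / full.sum()
    elif not kept.any():
        full[:] = 0.0
    final_sse = float(np.sum((target - P @ full) ** 2))
    return SignatureExposure(
        weights={name: float(w) for name, w in zip(sigs.names, full)},
        unexplained=final_sse,
        n_mutations=spec.total,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a signature matrix TSV: first column ``context`` with labels
    like "A[C>T]G" (any row order), remaining columns one signature each.
    The 30-signature COSMIC v2 export follows this shape once its metadata
    columns are dropped; extra non-numeric columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    ctx_col = "context" if "context" in df.columns else df.columns[0]
    df = df.set_index(ctx_col)
    num = df.select_dtypes("number")
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise ValueError(f"signature matrix missing {len(missing)} contexts, "
                         f"e.g. {sorted(missing)[:3]}")
    profiles = num.loc[list(CONTEXT_LABELS)].to_numpy(float)
    return SignatureMatrix(names=list(num.columns), profiles=profiles)


def write_signature_matrix(sigs: SignatureMatrix, path: str | Path) -> None:
    pd.DataFrame(sigs.profiles, index=pd.Index(CONTEXT_LABELS, name="context"),
                 columns=sigs.names).to_csv(path, sep="\t")


def write_exposures(exposures: dict[str, SignatureExposure], path) -> None:
    """Per-sample exposures TSV (sample, signature, weight, unexplained, n)."""
    rows = []
    for sample, e in exposures.items():
        for name, w in e.weights.items():
            if w > 0:
                rows.append({"sample": sample, "signature": name,
                             "weight": round(w, 6),
                             "unexplained": round(e.unexplained, 8),
                             "n_mutations": e.n_mutations})
    pd.DataFrame(rows, columns=["sample", "signature", "weight",
                                "unexplained", "n_mutations"]
                 ).to_csv(path, sep="\t", index=False)
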