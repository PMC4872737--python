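"""96-context mutation spectra normalized by reference trinucleotide content.

Single-base substitutions are collapsed into the six pyrimidine-framed
classes (C>A, C>G, C>T, T>A, T>C, T>G) within their 5' and 3' flanking
bases — 6 x 16 = 96 categories, written ``X[R>A]Y``.  A substitution
whose reference base is a purine is reverse-complemented into the
pyrimidine frame, so both strands of the circular genome pool into the
same bin (the standard convention of mutational-signature analysis).

Raw bin counts are normalized by the frequency of the corresponding
reference trinucleotide context (both strands pooled) and rescaled to
percentages, so the profile answers "how often does this change occur
*per opportunity* in this genome" rather than reflecting the genome's
base composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .reference import MtReference, context_at, trinucleotide_frequencies

__all__ = [
    "SBS96",
    "SpectrumProfile",
    "bin_variant",
    "spectrum",
    "compare_spectra",
    "plot_spectrum",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: The 96 substitution-in-context categories in canonical order:
#: six pyrimidine classes, each over the 16 flanking-base combinations.
SBS96: list[str] = [
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
]

_BIN_INDEX = {cat: i for i, cat in enumerate(SBS96)}


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SpectrumProfile:
    """96-bin substitution spectrum of a sample group."""

    label: str
    raw_counts: np.ndarray  # (96,) non-negative integers
    normalized: np.ndarray  # (96,) percentages summing to 100 (or all 0)

    @property
    def total(self) -> int:
        return int(self.raw_counts.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": SBS96,
            "raw": self.raw_counts.astype(int),
            "normalized_pct": self.normalized,
        })

    def class_frequencies(self) -> dict[str, float]:
        """Normalized percentage aggregated over the 6 substitution classes."""
        out = {}
        for k, cls in enumerate(SUBSTITUTION_CLASSES):
            out[cls] = float(self.normalized[16 * k: 16 * (k + 1)].sum())
        return out


def bin_variant(ref_genome: MtReference, pos: int, ref: str, alt: str) -> str:
    """Assign one SNV to its pyrimidine-framed substitution-in-context bin.

    The reference base at ``pos`` must equal ``ref``; purine-reference
    substitutions are reverse-complemented (change and flanks) into the
    pyrimidine frame.  Variants whose context contains an N cannot be
    binned and raise ``ValueError``.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(
            f"not a single-base substitution: {ref}>{alt} at {pos}"
        )
    genome_base = ref_genome.base_at(pos)
    if genome_base != ref:
        raise ValueError(
            f"reference mismatch at position {pos}: variant says {ref}, "
            f"genome says {genome_base}"
        )
    ctx = context_at(ref_genome, pos)
    if "N" in ctx:
        raise ValueError(f"context {ctx} at position {pos} contains N")
    if ref in "AG":  # purine frame: flip to the pyrimidine strand
        ctx = _revcomp(ctx)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


def _context_opportunity(ref_genome: MtReference) -> np.ndarray:
    """Per-bin reference context frequency, both strands pooled.

    Bin ``X[R>A]Y`` is normalized by freq(XRY) + freq(revcomp(XRY)).
    """
    freqs = trinucleotide_frequencies(ref_genome)
    opp = np.zeros(len(SBS96))
    for i, cat in enumerate(SBS96):
        ctx = cat[0] + cat[2] + cat[6]
        opp[i] = freqs.get(ctx, 0.0) + freqs.get(_revcomp(ctx), 0.0)
    return opp


def spectrum(
    variants: pd.DataFrame,
    ref_genome: MtReference,
    label: str = "",
) -> SpectrumProfile:
    """Normalized 96-bin spectrum of a group of SNVs.

    ``variants`` needs ``pos, ref, alt`` columns; indels and N-context
    variants are ignored.  Each bin's raw count is divided by the
    reference's pooled context frequency for that bin and the result is
    rescaled to percentages.  A count in a bin whose context never occurs
    in the same reference is impossible and raises ``ValueError``.
    """
    raw = np.zeros(len(SBS96), dtype=int)
    for r in variants.itertuples():
        if len(r.ref) != 1 or len(r.alt) != 1:
            continue
        if r.ref not in "ACGT" or r.alt not in "ACGT":
            continue
        try:
            cat = bin_variant(ref_genome, r.pos, r.ref, r.alt)
        except ValueError as exc:
            if "contains N" in str(exc):
                continue
            raise
        raw[_BIN_INDEX[cat]] += 1

    opp = _context_opportunity(ref_genome)
    impossible = (raw > 0) & (opp == 0)
    if impossible.any():
        cat = SBS96[int(np.flatnonzero(impossible)[0])]
        raise ValueError(
            f"bin {cat} has counts but its context is absent from the "
            f"reference {ref_genome.name!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(opp > 0, raw / np.where(opp > 0, opp, 1.0), 0.0)
    total = rate.sum()
    normalized = 100.0 * rate / total if total > 0 else np.zeros_like(rate)
    return SpectrumProfile(label=label, raw_counts=raw, normalized=normalized)


def split_primary_relapse(
    classified: pd.DataFrame,
    threshold: float = 0.02,
    min_depth: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor-specific SNVs present in the primary vs in any relapse.

    A variant present in both groups contributes to both (the groups are
    "present in P" and "present in R", not a partition).  Input is a
    classified cohort table with per-sample ``af_<role>``/``dp_<role>``
    columns.
    """
    from .variants import _presence

    ts = classified[classified["category"] == "tumor_specific"]
    in_p = _presence(ts, "P", threshold, min_depth)
    relapse_labs = [c[3:] for c in ts.columns if c.startswith("af_R")]
    in_r = pd.Series(False, index=ts.index)
    for lab in relapse_labs:
        in_r |= _presence(ts, lab, threshold, min_depth)
    return ts[in_p].reset_index(drop=True), ts[in_r].reset_index(drop=True)


def compare_spectra(a: SpectrumProfile, b: SpectrumProfile) -> dict:
    """Cosine similarity and per-class aggregates of two profiles.

    Both profiles live on the same canonical bin order by construction;
    empty profiles yield a similarity of ``nan``.
    """
    va, vb = a.normalized, b.normalized
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    cosine = float(va @ vb / (na * nb)) if na > 0 and nb > 0 else float("nan")
    return {
        "labels": [a.label, b.label],
        "cosine_similarity": cosine,
        "class_frequencies": {
            a.label or "a": a.class_frequencies(),
            b.label or "b": b.class_frequencies(),
        },
    }


def plot_spectrum(profiles: Iterable[SpectrumProfile], path=None):
    """Bar-plot one or more 96-bin profiles (one panel per profile)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = list(profiles)
    fig, axes = plt.subplots(
        len(profiles), 1, figsize=(14, 2.8 * len(profiles)), squeeze=False
    )
    colors = {
        "C>A": "#03bcee", "C>G": "#010101", "C>T": "#e32926",
        "T>A": "#cac9c9", "T>C": "#a1ce63", "T>G": "#ebc6c4",
    }
    x = np.arange(len(SBS96))
    bar_colors = [colors[c[2:5]] for c in SBS96]
    for ax, prof in zip(axes[:, 0], profiles):
        ax.bar(x, prof.normalized, color=bar_colors, width=0.8)
        ax.set_ylabel(f"{prof.label}\n% (normalized)")
        ax.set_xlim(-1, len(SBS96))
        ax.set_xticks(x)
        ax.set_xticklabels(
            [c[0] + c[2] + c[6] for c in SBS96], rotation=90, fontsize=4
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
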