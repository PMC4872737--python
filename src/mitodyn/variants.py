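"""Variant tables, abundance/coverage filters and germline vs tumor-specific calls.

The unit of input is a per-sample table of mitochondrial variant calls
(position, ref allele, alt allele, alt-allele fraction, read depth), the
tabular output of an upstream mitochondrial variant screen.  Within a
patient, samples are organized as a triplet — normal tissue, primary
tumor and one or more relapse tumors — and every observed variant key is
classified exactly once:

* **germline** — present in the patient's normal tissue at or above the
  abundance threshold (with passing depth);
* **tumor_specific** — below threshold or absent in normal, present in at
  least one tumor sample at or above threshold;
* **uninformative** — the normal sample lacks passing depth at the
  position, so germline status cannot be decided.  These are reported but
  excluded from both categories.

Thresholds follow the convention of heteroplasmy screens: coverage must
strictly exceed ``min_depth`` (default 50 reads), and abundance must
reach 2% for classification and 1% for the more permissive counting used
by the trend analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_COLUMNS",
    "FilterConfig",
    "PatientTriplet",
    "read_variant_table",
    "read_manifest",
    "read_catalog",
    "build_triplets",
    "apply_filters",
    "classify_patient",
    "annotate_known",
    "count_table",
    "count_summary",
]

#: Canonical column order of a sample variant table.
TABLE_COLUMNS = ["sample", "pos", "ref", "alt", "af", "dp"]

KEY_COLUMNS = ["pos", "ref", "alt"]


@dataclass(frozen=True)
class FilterConfig:
    """Coverage and abundance thresholds.

    ``min_depth`` is exclusive: a call needs *more than* this many reads.
    ``abundance_classify`` (default 2%) gates germline / tumor-specific
    classification; ``abundance_dynamics`` (default 1%) gates the counts
    entering the trend statistics and the phylogeny matrix.
    """

    min_depth: int = 50
    abundance_classify: float = 0.02
    abundance_dynamics: float = 0.01

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.abundance_dynamics <= self.abundance_classify < 1:
            raise ValueError(
                "need 0 < abundance_dynamics <= abundance_classify < 1, got "
                f"{self.abundance_dynamics} / {self.abundance_classify}"
            )

    def threshold(self, purpose: str) -> float:
        if purpose == "classify":
            return self.abundance_classify
        if purpose == "dynamics":
            return self.abundance_dynamics
        raise ValueError(f"unknown filter purpose {purpose!r}")


@dataclass
class PatientTriplet:
    """One patient's normal / primary / relapse sample tables.

    ``relapses`` is ordered by clinical time (R1, R2, ...); at least one
    relapse is required.
    """

    patient_id: str
    normal: pd.DataFrame
    primary: pd.DataFrame
    relapses: list[pd.DataFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.relapses:
            raise ValueError(f"patient {self.patient_id!r} has no relapse sample")

    @property
    def n_relapses(self) -> int:
        return len(self.relapses)

    @property
    def tumor_labels(self) -> list[str]:
        return ["P"] + [f"R{i + 1}" for i in range(self.n_relapses)]

    def samples(self) -> dict[str, pd.DataFrame]:
        """All samples keyed by role label (N, P, R1..Rk)."""
        out = {"N": self.normal, "P": self.primary}
        for i, rel in enumerate(self.relapses):
            out[f"R{i + 1}"] = rel
        return out


# ---------------------------------------------------------------------------
# I/O


def _validate_table(df: pd.DataFrame, source: object) -> pd.DataFrame:
    df = df.copy()
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["af"] = pd.to_numeric(df["af"], errors="coerce")
    df["dp"] = pd.to_numeric(df["dp"], errors="coerce")
    for col in ("pos", "af", "dp"):
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{source}: malformed {col!r} value on line {bad[0] + 2}"
            )
    bad = df.index[(df["af"] < 0) | (df["af"] > 1)]
    if len(bad):
        raise ValueError(
            f"{source}: allele fraction outside [0, 1] on line {bad[0] + 2}"
        )
    bad = df.index[df["dp"] < 0]
    if len(bad):
        raise ValueError(f"{source}: negative depth on line {bad[0] + 2}")
    bad = df.index[df["ref"].astype(str) == df["alt"].astype(str)]
    if len(bad):
        raise ValueError(
            f"{source}: ref allele equals alt allele on line {bad[0] + 2}"
        )
    df["pos"] = df["pos"].astype(int)
    df["dp"] = df["dp"].astype(int)
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    dup = df.duplicated(subset=["sample"] + KEY_COLUMNS, keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"{source}: duplicate variant key "
            f"({first['pos']}, {first['ref']}, {first['alt']}) "
            f"in sample {first['sample']!r}"
        )
    return df[TABLE_COLUMNS].reset_index(drop=True)


def _read_delimited(source, **kwargs) -> pd.DataFrame:
    # comma/tab auto-detection via the python engine's sniffer
    return pd.read_csv(source, sep=None, engine="python", **kwargs)


def read_variant_table(
    source: Union[str, Path, io.TextIOBase],
    sample_id: str | None = None,
    reference_length: int | None = None,
) -> pd.DataFrame:
    """Read a sample variant table from TSV/CSV or a minimal VCF.

    The delimited dialect needs a header with columns
    ``sample, pos, ref, alt, af, dp`` (comma- or tab-separated,
    auto-detected).  Files ending in ``.vcf`` are parsed as single-sample
    VCF with ``AF``/``DP`` in INFO or the first sample's FORMAT fields.

    Parameters
    ----------
    sample_id:
        Overrides (delimited) or supplies (VCF) the sample identifier.
    reference_length:
        When given, positions outside ``1..reference_length`` are an error.
    """
    is_vcf = isinstance(source, (str, Path)) and str(source).endswith(".vcf")
    if is_vcf:
        df = _read_vcf(source, sample_id)
    else:
        df = _read_delimited(source, dtype=str)
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(
                f"{source}: missing required columns {sorted(missing)}"
            )
        if sample_id is not None:
            df["sample"] = sample_id
    df = _validate_table(df, source)
    if reference_length is not None:
        out = df.index[(df["pos"] < 1) | (df["pos"] > reference_length)]
        if len(out):
            raise ValueError(
                f"{source}: position {df.loc[out[0], 'pos']} outside "
                f"reference (1..{reference_length})"
            )
    return df


def _read_vcf(path: Union[str, Path], sample_id: str | None) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        name = sample_id or (vcf_samples[0] if vcf_samples else Path(path).stem)
        for rec in vcf:
            if rec.alts is None:
                continue
            af = rec.info.get("AF")
            dp = rec.info.get("DP")
            if (af is None or dp is None) and vcf_samples:
                fmt = rec.samples[vcf_samples[0]]
                af = af if af is not None else fmt.get("AF")
                dp = dp if dp is not None else fmt.get("DP")
            if af is None or dp is None:
                raise ValueError(
                    f"{path}: record at position {rec.pos} lacks AF/DP"
                )
            afs = af if isinstance(af, (tuple, list)) else (af,) * len(rec.alts)
            for alt, alt_af in zip(rec.alts, afs):
                rows.append(
                    {"sample": name, "pos": rec.pos, "ref": rec.ref,
                     "alt": alt, "af": float(alt_af), "dp": int(dp)}
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def read_manifest(source: Union[str, Path, io.TextIOBase]) -> pd.DataFrame:
    """Read a patient manifest (patient_id, sample_id, role).

    Roles are ``normal``, ``primary`` and ``relapse`` (or ``relapse_1``,
    ``relapse_2``, ... for multi-relapse patients; bare ``relapse`` means
    the single relapse).
    """
    df = _read_delimited(source, dtype=str)
    missing = {"patient_id", "sample_id", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"{source}: manifest missing columns {sorted(missing)}")
    return df


def read_catalog(source: Union[str, Path, io.TextIOBase]) -> pd.DataFrame:
    """Read a known-variant catalog (pos, ref, alt[, id])."""
    df = _read_delimited(source, dtype=str)
    missing = set(KEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{source}: catalog missing columns {sorted(missing)}")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    if df["pos"].isna().any():
        raise ValueError(f"{source}: malformed position in catalog")
    df["pos"] = df["pos"].astype(int)
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    return df


def load_sample_tables(
    manifest: pd.DataFrame,
    tables_path: Union[str, Path],
    reference_length: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Load every manifest sample's variant table.

    ``tables_path`` is either a directory holding one
    ``<sample_id>.tsv`` / ``.csv`` / ``.vcf`` per sample, or a single
    combined delimited file whose ``sample`` column carries the ids.
    """
    path = Path(tables_path)
    tables: dict[str, pd.DataFrame] = {}
    if path.is_dir():
        for sid in manifest["sample_id"]:
            for ext in (".tsv", ".csv", ".vcf"):
                cand = path / f"{sid}{ext}"
                if cand.exists():
                    tables[sid] = read_variant_table(
                        cand, sample_id=sid,
                        reference_length=reference_length,
                    )
                    break
            else:
                raise ValueError(f"no variant table found for sample {sid!r}")
    else:
        combined = read_variant_table(path, reference_length=reference_length)
        for sid, grp in combined.groupby("sample"):
            tables[str(sid)] = grp.reset_index(drop=True)
    return tables


def build_triplets(
    manifest: pd.DataFrame, tables: Mapping[str, pd.DataFrame]
) -> list[PatientTriplet]:
    """Assemble patient triplets from a manifest and per-sample tables."""
    triplets = []
    for patient_id, grp in manifest.groupby("patient_id", sort=True):
        normal = primary = None
        relapses: list[tuple[int, pd.DataFrame]] = []
        for _, row in grp.iterrows():
            if row["sample_id"] not in tables:
                raise ValueError(
                    f"sample {row['sample_id']!r} of patient {patient_id!r} "
                    "has no variant table"
                )
            tab = tables[row["sample_id"]]
            role = row["role"].lower()
            if role == "normal":
                normal = tab
            elif role == "primary":
                primary = tab
            elif role.startswith("relapse"):
                idx = int(role.split("_")[1]) if "_" in role else 1
                relapses.append((idx, tab))
            else:
                raise ValueError(f"unknown role {row['role']!r} in manifest")
        if normal is None or primary is None:
            raise ValueError(
                f"patient {patient_id!r} lacks a normal or primary sample"
            )
        relapses.sort(key=lambda t: t[0])
        triplets.append(
            PatientTriplet(
                patient_id=str(patient_id),
                normal=normal,
                primary=primary,
                relapses=[t[1] for t in relapses],
            )
        )
    return triplets


# ---------------------------------------------------------------------------
# Filtering and classification


def apply_filters(
    table: pd.DataFrame, cfg: FilterConfig, purpose: str = "classify"
) -> pd.DataFrame:
    """Retain calls with depth > ``min_depth`` and abundance >= the
    purpose's threshold.

    The number of calls removed by each rule is recorded in the result's
    ``attrs['removed']`` for reporting.
    """
    thr = cfg.threshold(purpose)
    depth_ok = table["dp"] > cfg.min_depth
    af_ok = table["af"] >= thr
    out = table[depth_ok & af_ok].reset_index(drop=True)
    out.attrs["removed"] = {
        "depth": int((~depth_ok).sum()),
        "abundance": int((depth_ok & ~af_ok).sum()),
    }
    return out


def classify_patient(triplet: PatientTriplet, cfg: FilterConfig) -> pd.DataFrame:
    """Classify every variant key observed in a patient's samples.

    Returns one row per variant key with columns ``patient_id, pos, ref,
    alt, category, occurrence`` plus per-sample ``af_<role>`` /
    ``dp_<role>`` columns (N, P, R1..Rk).  ``occurrence`` lists the tumor
    samples where the variant is present at the classification threshold,
    comma-separated.

    Normal-sample depth decides informativeness: if the normal sample
    carries a call at the variant's position that fails the depth filter,
    germline status cannot be decided and the variant is flagged
    ``uninformative``.  A position with no call in normal is taken as
    reference-covered (the upstream caller reports every non-reference
    site).
    """
    samples = triplet.samples()
    labels = list(samples)  # N, P, R1..
    thr = cfg.abundance_classify

    # index per sample: key -> (af, dp); plus low-depth positions in normal
    lookup: dict[str, dict[tuple, tuple[float, int]]] = {}
    for lab, tab in samples.items():
        lookup[lab] = {
            (r.pos, r.ref, r.alt): (r.af, r.dp) for r in tab.itertuples()
        }
    normal_lowdepth_pos = {
        r.pos for r in triplet.normal.itertuples() if r.dp <= cfg.min_depth
    }

    def present(lab: str, key: tuple) -> bool:
        hit = lookup[lab].get(key)
        return hit is not None and hit[1] > cfg.min_depth and hit[0] >= thr

    keys = sorted({k for lab in labels for k in lookup[lab]})
    rows = []
    for key in keys:
        pos, ref, alt = key
        tumor_occ = [lab for lab in labels[1:] if present(lab, key)]
        if present("N", key):
            category = "germline"
        elif pos in normal_lowdepth_pos:
            category = "uninformative"
            tumor_occ = []
        elif tumor_occ:
            category = "tumor_specific"
        else:
            # observed only below threshold everywhere: not classifiable
            category = "subthreshold"
            tumor_occ = []
        row = {
            "patient_id": triplet.patient_id,
            "pos": pos, "ref": ref, "alt": alt,
            "category": category,
            "occurrence": ",".join(tumor_occ),
        }
        for lab in labels:
            hit = lookup[lab].get(key)
            row[f"af_{lab}"] = hit[0] if hit else 0.0
            row[f"dp_{lab}"] = hit[1] if hit else -1  # -1: no call reported
        rows.append(row)
    cols = ["patient_id", "pos", "ref", "alt", "category", "occurrence"]
    cols += [f"{p}_{lab}" for lab in labels for p in ("af", "dp")]
    out = pd.DataFrame(rows, columns=cols)
    out = out[out["category"] != "subthreshold"].reset_index(drop=True)
    return out


def annotate_known(
    classified: pd.DataFrame, catalog: pd.DataFrame | None
) -> pd.DataFrame:
    """Flag each classified variant as known/novel against a local catalog.

    Without a catalog every variant is ``unannotated``.
    """
    out = classified.copy()
    if catalog is None:
        out["known_status"] = "unannotated"
        return out
    known = {
        (r.pos, r.ref, r.alt) for r in catalog.itertuples()
    }
    out["known_status"] = [
        "known" if (r.pos, r.ref, r.alt) in known else "novel"
        for r in out.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# Counting


def _presence(classified: pd.DataFrame, lab: str, threshold: float,
              min_depth: int) -> pd.Series:
    af = classified.get(f"af_{lab}")
    if af is None:
        return pd.Series(False, index=classified.index)
    dp = classified[f"dp_{lab}"]
    # dp == -1 encodes "no call": absent by definition
    return (af >= threshold) & (dp > min_depth)


def count_table(
    classified_cohort: pd.DataFrame,
    threshold: float = 0.01,
    min_depth: int = 50,
    collapse_relapses: str = "union",
) -> pd.DataFrame:
    """Per-patient variant counts: tumor-specific and germline, in P and R.

    ``threshold`` sets the abundance at which presence in a sample is
    counted (the trend analyses use the permissive 1% cut).  Germline
    counts include the normal-tissue column (every germline variant is
    present in normal by definition of the category).  For patients with
    several relapses the R column is the union over relapse samples
    (``collapse_relapses='union'``) or the first relapse (``'first'``).
    """
    rows = []
    for patient_id, grp in classified_cohort.groupby("patient_id", sort=True):
        relapse_labs = sorted(
            (c[3:] for c in grp.columns
             if c.startswith("af_R") and grp[c].notna().any()),
            key=lambda s: int(s[1:]),
        )
        if collapse_relapses == "first":
            relapse_labs = relapse_labs[:1]
        in_p = _presence(grp, "P", threshold, min_depth)
        in_r = pd.Series(False, index=grp.index)
        for lab in relapse_labs:
            in_r |= _presence(grp, lab, threshold, min_depth)
        ts = grp["category"] == "tumor_specific"
        gl = grp["category"] == "germline"
        rows.append({
            "patient_id": patient_id,
            "ts_p": int((ts & in_p).sum()),
            "ts_r": int((ts & in_r).sum()),
            "germ_n": int(gl.sum()),
            "germ_p": int((gl & in_p).sum()),
            "germ_r": int((gl & in_r).sum()),
        })
    return pd.DataFrame(rows)


def count_summary(counts: pd.DataFrame) -> dict:
    """Cohort-level aggregates over a per-patient count table.

    Expects columns ``patient_id, ts_p, ts_r, germ_p, germ_r`` (the
    normal-tissue germline column is optional).  Per-tumor statistics
    pool the primary and relapse columns, i.e. run over ``2 * n_patients``
    tumor samples.
    """
    ts = np.concatenate([counts["ts_p"].to_numpy(), counts["ts_r"].to_numpy()])
    gl = np.concatenate([counts["germ_p"].to_numpy(),
                         counts["germ_r"].to_numpy()])
    diff = counts["ts_r"] - counts["ts_p"]
    has_ts = (counts["ts_p"] > 0) | (counts["ts_r"] > 0)
    n = len(counts)
    return {
        "n_patients": n,
        "tumor_specific": {
            "mean_per_tumor": float(ts.mean()),
            "min_per_tumor": int(ts.min()),
            "max_per_tumor": int(ts.max()),
        },
        "germline": {
            "mean_per_tumor": float(gl.mean()),
            "min_per_tumor": int(gl.min()),
            "max_per_tumor": int(gl.max()),
        },
        "n_patients_with_tumor_specific": int(has_ts.sum()),
        "pct_patients_with_tumor_specific": float(100.0 * has_ts.sum() / n),
        "n_positive_paired_difference": int((diff > 0).sum()),
        "mean_paired_difference": float(diff.mean()),
    }
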