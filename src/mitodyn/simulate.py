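"""Synthetic normal/primary/relapse cohorts with planted variant dynamics.

The generator emulates the qualitative structure of a relapsing-tumor
mitochondrial cohort: each patient carries a load of germline
heteroplasmic variants (present in normal tissue at high allele
fraction) that may drift below detection at successive disease stages,
and acquires tumor-specific variants at low allele fraction — a few in
the primary tumor and more at relapse.  Substitution types follow a
configurable 96-context weight vector whose default is
replication-type (C>T and T>C enriched), and every variant's true
category is recorded so the classification, trend, phylogeny and
spectrum stages can all be validated against ground truth.

Defaults mirror the scale of a 16-patient neuroblastoma relapse cohort:
~112 germline variants per patient, ~3 tumor-specific variants in the
primary and ~8 more gained at relapse, read depths around a mean
coverage of 212.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import MtReference, context_at
from .spectrum import SBS96
from .variants import TABLE_COLUMNS, PatientTriplet

__all__ = [
    "CohortSpec",
    "SimulatedCohort",
    "default_spectrum_weights",
    "synthetic_reference",
    "simulate_cohort",
    "simulate_multirelapse",
    "write_cohort",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def default_spectrum_weights() -> np.ndarray:
    """Replication-type substitution weights over the 96 bins.

    Transitions dominate (C>T and T>C each carry 35% of the mass, the
    four transversion classes 7.5% each), spread uniformly over the 16
    flanking-base combinations within each class.
    """
    class_mass = {"C>A": 0.075, "C>G": 0.075, "C>T": 0.35,
                  "T>A": 0.075, "T>C": 0.35, "T>G": 0.075}
    w = np.array([class_mass[cat[2:5]] / 16.0 for cat in SBS96])
    return w / w.sum()


def synthetic_reference(
    length: int = 16569, seed: int = 0, name: str = "synthetic_mt"
) -> MtReference:
    """Random circular mt-like reference (synthetic stand-in for a real
    mitochondrial genome) with a human-mtDNA-like base composition."""
    rng = np.random.default_rng(seed)
    # approximate heavy-strand composition of human mtDNA
    bases = rng.choice(list("ACGT"), size=length,
                       p=[0.309, 0.313, 0.131, 0.247])
    return MtReference(name=name, sequence="".join(bases))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Rates are expectations of Poisson counts; allele fractions are drawn
    uniformly from the given ranges with a small per-sample jitter, and
    are kept clear of the 2% classification threshold so that ground
    truth is unambiguous at default filter settings.
    """

    n_patients: int = 16
    relapses_per_patient: int = 1
    germline_rate: float = 112.0       # expected germline variants / patient
    germline_loss: float = 0.15        # per-stage loss probability
    ts_rate_primary: float = 3.0       # expected TS variants arising in P
    ts_rate_relapse: float = 8.0       # expected TS variants gained per R
    ts_persistence: float = 0.5        # P-variant carried to each relapse
    germline_af: tuple[float, float] = (0.30, 0.95)
    ts_af: tuple[float, float] = (0.04, 0.25)
    af_jitter: float = 0.01            # sd of per-sample gaussian jitter
    mean_depth: float = 212.0
    spectrum_weights: np.ndarray | None = None  # default replication-type
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (self.germline_rate, self.ts_rate_primary,
                  self.ts_rate_relapse):
            if r < 0:
                raise ValueError("rates must be >= 0")
        for f in (self.germline_loss, self.ts_persistence):
            if not 0 <= f <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spectrum_weights is not None:
            w = np.asarray(self.spectrum_weights)
            if w.shape != (96,) or not np.isclose(w.sum(), 1.0):
                raise ValueError("spectrum_weights must be 96 values summing to 1")

    @property
    def weights(self) -> np.ndarray:
        if self.spectrum_weights is None:
            return default_spectrum_weights()
        return np.asarray(self.spectrum_weights, dtype=float)


@dataclass
class SimulatedCohort:
    """Generated tables plus per-variant ground truth."""

    triplets: list[PatientTriplet]
    tables: dict[str, pd.DataFrame]      # sample_id -> variant table
    manifest: pd.DataFrame               # patient_id, sample_id, role
    truth: pd.DataFrame                  # patient_id, pos, ref, alt, ...
    spec: CohortSpec


def _context_positions(ref: MtReference) -> dict[str, np.ndarray]:
    by_ctx: dict[str, list[int]] = {}
    for pos in range(1, ref.length + 1):
        ctx = context_at(ref, pos)
        if "N" not in ctx:
            by_ctx.setdefault(ctx, []).append(pos)
    return {k: np.array(v) for k, v in by_ctx.items()}


def _draw_variant(
    rng: np.random.Generator,
    weights: np.ndarray,
    ctx_map: dict[str, np.ndarray],
    used: set[tuple[int, str, str]],
) -> tuple[int, str, str]:
    """One SNV key with substitution type drawn from the 96-bin weights.

    The bin fixes the pyrimidine-frame context and alt base; a genome
    position carrying that context on either strand is chosen uniformly
    (purine-strand hits are complemented back to genome coordinates).
    """
    def _key_at(fwd, rev, n_f, k):
        if k < n_f:
            return (int(fwd[k]), ref_base, alt_base)
        return (
            int(rev[k - n_f]),
            ref_base.translate(_COMPLEMENT),
            alt_base.translate(_COMPLEMENT),
        )

    for _ in range(200):
        b = int(rng.choice(len(SBS96), p=weights))
        cat = SBS96[b]
        five, ref_base, alt_base, three = cat[0], cat[2], cat[4], cat[6]
        ctx = five + ref_base + three
        fwd = ctx_map.get(ctx)
        rev = ctx_map.get(_revcomp(ctx))
        n_f = 0 if fwd is None else len(fwd)
        n_r = 0 if rev is None else len(rev)
        if n_f + n_r == 0:
            continue
        # retry positions within the bin so collisions with already-used
        # keys do not skew the realized bin distribution
        for _ in range(30):
            key = _key_at(fwd, rev, n_f, int(rng.integers(0, n_f + n_r)))
            if key not in used:
                used.add(key)
                return key
        free = [
            key for k in range(n_f + n_r)
            if (key := _key_at(fwd, rev, n_f, k)) not in used
        ]
        if free:
            key = free[int(rng.integers(0, len(free)))]
            used.add(key)
            return key
    raise RuntimeError(
        "could not place a variant; reference too small for requested rates"
    )


def _af(rng, base_af: float, jitter: float, lo: float = 0.03,
        hi: float = 0.98) -> float:
    return float(np.clip(base_af + rng.normal(0.0, jitter), lo, hi))


def _simulate_patient(
    rng: np.random.Generator,
    spec: CohortSpec,
    ctx_map: dict[str, np.ndarray],
    patient_id: str,
    n_relapses: int,
) -> tuple[dict[str, list[dict]], list[dict]]:
    """Rows per role label (N, P, R1..Rk) and ground-truth records."""
    labels = ["N", "P"] + [f"R{i + 1}" for i in range(n_relapses)]
    rows: dict[str, list[dict]] = {lab: [] for lab in labels}
    truth: list[dict] = []
    used: set[tuple[int, str, str]] = set()
    w = spec.weights

    def emit(lab: str, key, af0: float, lo: float) -> None:
        pos, ref_a, alt_a = key
        rows[lab].append({
            "sample": f"{patient_id}_{lab}",
            "pos": pos, "ref": ref_a, "alt": alt_a,
            "af": _af(rng, af0, spec.af_jitter, lo=lo),
            "dp": int(rng.poisson(spec.mean_depth)),
        })

    # germline variants: present in normal, per-stage drift/loss
    for _ in range(rng.poisson(spec.germline_rate)):
        key = _draw_variant(rng, w, ctx_map, used)
        af0 = float(rng.uniform(*spec.germline_af))
        emit("N", key, af0, lo=0.05)
        in_primary = rng.random() >= spec.germline_loss
        if in_primary:
            emit("P", key, af0, lo=0.05)
        for i in range(n_relapses):
            if in_primary and rng.random() >= spec.germline_loss:
                emit(f"R{i + 1}", key, af0, lo=0.05)
        truth.append({
            "patient_id": patient_id, "pos": key[0], "ref": key[1],
            "alt": key[2], "true_category": "germline", "origin": "germline",
        })

    # tumor-specific variants arising in the primary
    for _ in range(rng.poisson(spec.ts_rate_primary)):
        key = _draw_variant(rng, w, ctx_map, used)
        af0 = float(rng.uniform(*spec.ts_af))
        emit("P", key, af0, lo=0.03)
        for i in range(n_relapses):
            if rng.random() < spec.ts_persistence:
                emit(f"R{i + 1}", key, af0, lo=0.03)
        truth.append({
            "patient_id": patient_id, "pos": key[0], "ref": key[1],
            "alt": key[2], "true_category": "tumor_specific",
            "origin": "ts_primary",
        })

    # tumor-specific variants gained privately at each relapse
    for i in range(n_relapses):
        for _ in range(rng.poisson(spec.ts_rate_relapse)):
            key = _draw_variant(rng, w, ctx_map, used)
            af0 = float(rng.uniform(*spec.ts_af))
            emit(f"R{i + 1}", key, af0, lo=0.03)
            truth.append({
                "patient_id": patient_id, "pos": key[0], "ref": key[1],
                "alt": key[2], "true_category": "tumor_specific",
                "origin": f"ts_relapse_{i + 1}",
            })

    return rows, truth


def _to_table(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


def simulate_cohort(spec: CohortSpec, ref: MtReference) -> SimulatedCohort:
    """Generate a full cohort of patient triplets with ground truth."""
    expected = (spec.germline_rate + spec.ts_rate_primary
                + spec.relapses_per_patient * spec.ts_rate_relapse)
    if expected > ref.length:
        raise ValueError(
            f"expected {expected:.0f} variants per patient exceeds the "
            f"reference length {ref.length}"
        )
    rng = np.random.default_rng(spec.seed)
    ctx_map = _context_positions(ref)
    triplets, tables, manifest_rows, truth_frames = [], {}, [], []
    for p in range(spec.n_patients):
        pid = f"SIM{p + 1:03d}"
        rows, truth = _simulate_patient(
            rng, spec, ctx_map, pid, spec.relapses_per_patient
        )
        role_names = {"N": "normal", "P": "primary"}
        triplet_tabs = {}
        for lab, rr in rows.items():
            sid = f"{pid}_{lab}"
            tab = _to_table(rr)
            tables[sid] = tab
            triplet_tabs[lab] = tab
            role = role_names.get(
                lab, f"relapse_{lab[1:]}" if spec.relapses_per_patient > 1
                else "relapse"
            )
            manifest_rows.append(
                {"patient_id": pid, "sample_id": sid, "role": role}
            )
        triplets.append(PatientTriplet(
            patient_id=pid,
            normal=triplet_tabs["N"],
            primary=triplet_tabs["P"],
            relapses=[triplet_tabs[f"R{i + 1}"]
                      for i in range(spec.relapses_per_patient)],
        ))
        truth_frames.append(pd.DataFrame(truth))
    truth = (pd.concat([t for t in truth_frames if not t.empty],
                       ignore_index=True)
             if any(not t.empty for t in truth_frames)
             else pd.DataFrame(columns=["patient_id", "pos", "ref", "alt",
                                        "true_category", "origin"]))
    return SimulatedCohort(
        triplets=triplets,
        tables=tables,
        manifest=pd.DataFrame(manifest_rows),
        truth=truth,
        spec=spec,
    )


def simulate_multirelapse(
    spec: CohortSpec,
    ref: MtReference,
    lineage_sizes: tuple[int, int] = (4, 1),
    shared_rate: float = 30.0,
    private_rate: float = 5.0,
) -> tuple[PatientTriplet, pd.DataFrame, frozenset[str]]:
    """One patient with >= 3 relapses split into two planted lineages.

    On top of the usual germline and tumor-specific machinery, each
    lineage receives Poisson(``shared_rate``) variants shared by all its
    relapses and absent from the other lineage (mutually exclusive
    lineage markers), and every relapse Poisson(``private_rate``)
    private variants.  Returns the triplet, a ground-truth table with a
    ``lineage`` column, and the planted leaf bipartition (the first
    lineage's relapse labels) for checking tree reconstruction.
    """
    n_relapses = sum(lineage_sizes)
    if n_relapses < 3:
        raise ValueError("need >= 3 relapses for a multi-relapse patient")
    rng = np.random.default_rng(spec.seed)
    ctx_map = _context_positions(ref)
    pid = "SIMMR"
    rows, truth = _simulate_patient(rng, spec, ctx_map, pid, n_relapses)
    used = {(t["pos"], t["ref"], t["alt"]) for t in truth}
    labels = [f"R{i + 1}" for i in range(n_relapses)]
    lineages = [labels[: lineage_sizes[0]], labels[lineage_sizes[0]:]]
    w = spec.weights

    def emit(lab: str, key, af0: float) -> None:
        pos, ref_a, alt_a = key
        rows[lab].append({
            "sample": f"{pid}_{lab}",
            "pos": pos, "ref": ref_a, "alt": alt_a,
            "af": _af(rng, af0, spec.af_jitter, lo=0.03),
            "dp": int(rng.poisson(spec.mean_depth)),
        })

    for li, members in enumerate(lineages):
        for _ in range(rng.poisson(shared_rate)):
            key = _draw_variant(rng, w, ctx_map, used)
            af0 = float(rng.uniform(*spec.ts_af))
            for lab in members:
                emit(lab, key, af0)
            truth.append({
                "patient_id": pid, "pos": key[0], "ref": key[1],
                "alt": key[2], "true_category": "tumor_specific",
                "origin": f"lineage_{li + 1}_shared",
            })
        for lab in members:
            for _ in range(rng.poisson(private_rate)):
                key = _draw_variant(rng, w, ctx_map, used)
                af0 = float(rng.uniform(*spec.ts_af))
                emit(lab, key, af0)
                truth.append({
                    "patient_id": pid, "pos": key[0], "ref": key[1],
                    "alt": key[2], "true_category": "tumor_specific",
                    "origin": f"lineage_{li + 1}_private_{lab}",
                })

    truth_df = pd.DataFrame(truth)
    lineage_of = {}
    for li, members in enumerate(lineages):
        for lab in members:
            lineage_of[lab] = li + 1
    truth_df["lineage"] = [
        lineage_of.get(o.split("_private_")[-1], 0)
        if "private" in o else
        (int(o.split("_")[1]) if o.startswith("lineage") else 0)
        for o in truth_df["origin"]
    ]
    triplet = PatientTriplet(
        patient_id=pid,
        normal=_to_table(rows["N"]),
        primary=_to_table(rows["P"]),
        relapses=[_to_table(rows[lab]) for lab in labels],
    )
    planted = frozenset(f"{pid}_{lab}" for lab in lineages[0])
    return triplet, truth_df, planted


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write per-sample variant TSVs, the manifest and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, tab in cohort.tables.items():
        p = out / f"{sid}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        paths[sid] = p
    mpath = out / "manifest.tsv"
    cohort.manifest.to_csv(mpath, sep="\t", index=False)
    paths["manifest"] = mpath
    tpath = out / "truth.tsv"
    cohort.truth.to_csv(tpath, sep="\t", index=False)
    paths["truth"] = tpath
    return paths
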