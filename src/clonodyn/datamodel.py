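"""Validated data model for longitudinal mutation count tables, plus readers/writers.

Input is a long (tidy) table with one row per (mutation, sample): alternative
and total read counts, sample purity and collection time, and optionally the
local total copy number and mutation multiplicity. Every mutation must be
observed in every sample — a ragged grid is an error, never silently imputed.
Collection times are normalized onto [0, 1] so kernel time scales are
comparable across studies regardless of the raw unit (days, months, years).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ccf import LocusContext, clonal_vaf_coefficient, estimate_multiplicity

__all__ = [
    "TableSchemaError",
    "TableValidationError",
    "SampleInfo",
    "MutationTable",
    "normalize_times",
    "read_mutation_table",
    "write_mutation_table",
    "write_fit_report",
]

REQUIRED_COLUMNS = ("mutationID", "sampleID", "altCounts", "purity", "time")


class TableSchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class TableValidationError(ValueError):
    """The table violates a structural invariant (ragged grid, bad counts...)."""


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: identifier, raw and normalized time, purity."""

    sample_id: str
    time_raw: float
    time_unit: float
    purity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise TableValidationError(
                f"sample {self.sample_id!r}: purity must be in (0, 1], got {self.purity}"
            )
        if not 0.0 <= self.time_unit <= 1.0:
            raise TableValidationError("normalized time must lie in [0, 1]")


def normalize_times(times_raw) -> np.ndarray:
    """Affine map of strictly increasing raw times onto [0, 1].

    t -> (t - t_1) / (t_M - t_1); a single sample maps to [0]. Invariant to
    affine rescaling of the raw times (months vs days give the same output).
    """
    t = np.asarray(times_raw, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise TableValidationError("times must be a non-empty 1-d sequence")
    if t.size == 1:
        return np.zeros(1)
    if np.any(np.diff(t) <= 0):
        raise TableValidationError(f"times must be strictly increasing, got {t.tolist()}")
    return (t - t[0]) / (t[-1] - t[0])


@dataclass
class MutationTable:
    """Complete N x M grid of read counts with per-sample metadata.

    Arrays are indexed [mutation, sample] with samples ordered by collection
    time. ``multiplicity`` entries of 0 mean "unset" (to be estimated from the
    pooled VAF via the integer multiplicity rule).
    """

    mutation_ids: list[str]
    samples: list[SampleInfo]
    alt: np.ndarray
    total: np.ndarray
    cn_total: np.ndarray
    multiplicity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        N, M = len(self.mutation_ids), len(self.samples)
        if N < 1 or M < 1:
            raise TableValidationError("need at least one mutation and one sample")
        if self.multiplicity is None:
            self.multiplicity = np.zeros((N, M), dtype=np.int64)
        for name in ("alt", "total", "cn_total", "multiplicity"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (N, M):
                raise TableValidationError(f"{name} must have shape ({N}, {M}), got {arr.shape}")
            if not np.issubdtype(arr.dtype, np.integer):
                raise TableValidationError(f"{name} must hold integers")
            setattr(self, name, arr.astype(np.int64))
        if np.any(self.alt < 0):
            raise TableValidationError("alt counts must be non-negative")
        if np.any(self.total < 1):
            raise TableValidationError("total counts must be positive")
        if np.any(self.alt > self.total):
            bad = np.argwhere(self.alt > self.total)
            i, j = bad[0]
            raise TableValidationError(
                f"alt > total for ({self.mutation_ids[i]}, {self.samples[j].sample_id})"
            )
        if np.any(self.cn_total < 1):
            raise TableValidationError("total copy number must be a positive integer")
        if np.any(self.multiplicity > self.cn_total):
            raise TableValidationError("multiplicity may not exceed total copy number")
        if np.any(self.multiplicity < 0):
            raise TableValidationError("multiplicity must be positive (0 marks unset)")
        times = np.array([s.time_unit for s in self.samples])
        if M >= 2 and (not np.isclose(times[0], 0.0) or not np.isclose(times[-1], 1.0)
                       or np.any(np.diff(times) <= 0)):
            raise TableValidationError("normalized sample times must increase from 0 to 1")

    # -- convenience views ---------------------------------------------------

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_unit for s in self.samples])

    @property
    def purities(self) -> np.ndarray:
        return np.array([s.purity for s in self.samples])

    def vaf(self) -> np.ndarray:
        return self.alt / self.total

    def resolved_multiplicity(self, per_sample: bool = False) -> np.ndarray:
        """Multiplicities with unset entries estimated from observed VAFs.

        By default the estimate uses the depth-weighted VAF pooled across
        samples, keeping the multiplicity of a mutation constant over time
        (consistent with the no-subclonal-CNV assumption); ``per_sample=True``
        estimates from each sample's own VAF instead. Pre-specified
        multiplicities are used verbatim.
        """
        out = self.multiplicity.copy()
        purities = self.purities
        for i in range(self.n_mutations):
            for j in range(self.n_samples):
                if out[i, j] == 0:
                    if per_sample:
                        vaf = self.alt[i, j] / self.total[i, j]
                    else:
                        vaf = self.alt[i].sum() / self.total[i].sum()
                    out[i, j] = estimate_multiplicity(vaf, purities[j], int(self.cn_total[i, j]))
        return out

    def zeta(self, per_sample_multiplicity: bool = False) -> np.ndarray:
        """N x M matrix of clonal-VAF coefficients zeta_ij."""
        d = self.resolved_multiplicity(per_sample=per_sample_multiplicity)
        out = np.empty((self.n_mutations, self.n_samples))
        for j, s in enumerate(self.samples):
            for i in range(self.n_mutations):
                ctx = LocusContext(
                    purity=s.purity,
                    copy_number=int(self.cn_total[i, j]),
                    multiplicity=int(d[i, j]),
                )
                out[i, j] = clonal_vaf_coefficient(ctx)
        return out


def _require_columns(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TableSchemaError(f"missing required column {col!r}")
    if "totalCounts" not in df.columns and "refCounts" not in df.columns:
        raise TableSchemaError("need either a 'totalCounts' or a 'refCounts' column")


def _as_int_column(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = df[col].to_numpy()
    as_float = np.asarray(vals, dtype=float)
    if np.any(~np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
        raise TableSchemaError(f"column {col!r} must contain integers")
    return as_float.astype(np.int64)


def table_from_dataframe(df: pd.DataFrame) -> MutationTable:
    """Validate a long-format dataframe and assemble the N x M grid."""
    _require_columns(df)
    df = df.copy()
    df["altCounts"] = _as_int_column(df, "altCounts")
    if "totalCounts" in df.columns:
        df["totalCounts"] = _as_int_column(df, "totalCounts")
    else:
        df["totalCounts"] = df["altCounts"] + _as_int_column(df, "refCounts")
    df["cnTotal"] = _as_int_column(df, "cnTotal") if "cnTotal" in df.columns else 2
    df["cnMultiplicity"] = (
        _as_int_column(df, "cnMultiplicity") if "cnMultiplicity" in df.columns else 0
    )

    # per-sample metadata must be constant within sample_id
    samples = []
    for sid, grp in df.groupby("sampleID", sort=False):
        for col in ("purity", "time"):
            if grp[col].nunique() != 1:
                raise TableValidationError(
                    f"sample {sid!r}: column {col!r} is not constant across rows"
                )
        samples.append((str(sid), float(grp["time"].iloc[0]), float(grp["purity"].iloc[0])))
    samples.sort(key=lambda s: s[1])
    raw_times = [s[1] for s in samples]
    unit_times = normalize_times(raw_times)
    infos = [
        SampleInfo(sample_id=sid, time_raw=traw, time_unit=float(tu), purity=p)
        for (sid, traw, p), tu in zip(samples, unit_times)
    ]

    mut_ids = list(dict.fromkeys(df["mutationID"].astype(str)))
    sid_index = {s.sample_id: j for j, s in enumerate(infos)}
    mut_index = {m: i for i, m in enumerate(mut_ids)}
    N, M = len(mut_ids), len(infos)
    seen = np.zeros((N, M), dtype=bool)
    alt = np.zeros((N, M), dtype=np.int64)
    total = np.zeros((N, M), dtype=np.int64)
    cn = np.full((N, M), 2, dtype=np.int64)
    mult = np.zeros((N, M), dtype=np.int64)
    for row in df.itertuples(index=False):
        i = mut_index[str(row.mutationID)]
        j = sid_index[str(row.sampleID)]
        if seen[i, j]:
            raise TableValidationError(
                f"duplicate row for ({mut_ids[i]}, {infos[j].sample_id})"
            )
        seen[i, j] = True
        alt[i, j] = row.altCounts
        total[i, j] = row.totalCounts
        cn[i, j] = row.cnTotal
        mult[i, j] = row.cnMultiplicity
    if not seen.all():
        missing = [
            (mut_ids[i], infos[j].sample_id) for i, j in np.argwhere(~seen)
        ]
        raise TableValidationError(f"ragged grid; missing (mutation, sample) pairs: {missing}")
    return MutationTable(mut_ids, infos, alt, total, cn, mult)


def read_mutation_table(path, dialect: str | None = None) -> MutationTable:
    """Read a TSV/CSV long-format table into a validated MutationTable.

    The dialect is inferred from the file suffix when not given (.csv -> comma,
    anything else -> tab).
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError("dialect must be 'tsv' or 'csv'")
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return table_from_dataframe(df)


def write_mutation_table(table: MutationTable, path, dialect: str | None = None) -> None:
    """Write a MutationTable back to its long-format TSV/CSV representation."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if dialect == "csv" else "\t"
    rows = []
    for j, s in enumerate(table.samples):
        for i, mid in enumerate(table.mutation_ids):
            rows.append(
                {
                    "mutationID": mid,
                    "sampleID": s.sample_id,
                    "altCounts": int(table.alt[i, j]),
                    "totalCounts": int(table.total[i, j]),
                    "purity": s.purity,
                    "time": s.time_raw,
                    "cnTotal": int(table.cn_total[i, j]),
                    "cnMultiplicity": int(table.multiplicity[i, j]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_fit_report(fit, report, out_dir) -> dict[str, Path]:
    """Write assignment CSV, trajectory CSV and run-metadata JSON for a fit.

    Returns a mapping of artifact name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    assign = pd.DataFrame(
        report.membership,
        columns=[f"p_cluster{k}" for k in report.kept_clusters],
    )
    assign.insert(0, "mutationID", report.mutation_ids)
    assign.insert(1, "hardLabel", report.hard_labels)
    assign_path = out_dir / "assignments.csv"
    assign.to_csv(assign_path, index=False)

    rows = []
    for k, curve in report.trajectories.items():
        for g in range(len(curve["time"])):
            rows.append(
                {
                    "cluster": k,
                    "time": curve["time"][g],
                    "ccf_median": curve["median"][g],
                    "ccf_lo": curve["lo"][g],
                    "ccf_hi": curve["hi"][g],
                }
            )
    traj_path = out_dir / "trajectories.csv"
    pd.DataFrame(rows).to_csv(traj_path, index=False)

    from . import __version__

    meta = {
        "package": "clonodyn",
        "version": __version__,
        "model": fit.spec.name,
        "truncation": fit.spec.truncation,
        "observation_family": fit.spec.observation.family,
        "seed": fit.seed,
        "final_elbo": fit.final_elbo,
        "final_elbo_se": fit.final_elbo_se,
        "iterations": fit.n_iterations,
        "converged": fit.converged,
        "kept_clusters": [int(k) for k in report.kept_clusters],
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"assignments": assign_path, "trajectories": traj_path, "metadata": meta_path}
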