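"""Compositional treatment of count tables: proportions and the log-ratio transform.

A count table is reduced to proportions (optionally after adding a pseudocount
to every cell to resolve zeros) and mapped to unconstrained coordinates by
taking log-ratios against a designated reference taxon.  The transform is a
bijection between the open simplex and R^(S-1); ``inverse_log_ratio`` recovers
proportions with ``rho_ref = 1 / (1 + sum_s exp(y_s))``, the self-consistent
normalization that makes every row sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "CountTable",
    "CompositionTable",
    "LogRatioTable",
    "counts_to_proportions",
    "log_ratio_transform",
    "inverse_log_ratio",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 0.5


def _check_labels(sample_ids: Sequence[str], taxon_ids: Sequence[str]) -> tuple[list, list]:
    sample_ids = list(sample_ids)
    taxon_ids = list(taxon_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample labels")
    if len(set(taxon_ids)) != len(taxon_ids):
        raise ValueError("duplicate taxon labels")
    return sample_ids, taxon_ids


@dataclass(frozen=True)
class CountTable:
    """Samples x taxa table of nonnegative integer counts."""

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    taxon_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("count table must be 2-dimensional")
        n, s = values.shape
        if n < 1 or s < 2:
            raise ValueError(f"need at least 1 sample and 2 taxa, got shape {values.shape}")
        if np.any(values < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        object.__setattr__(self, "values", values.astype(np.int64))
        sample_ids = list(self.sample_ids) or [f"sample{i + 1}" for i in range(n)]
        taxon_ids = list(self.taxon_ids) or [f"taxon{j + 1}" for j in range(s)]
        if len(sample_ids) != n or len(taxon_ids) != s:
            raise ValueError("label lengths do not match table shape")
        sample_ids, taxon_ids = _check_labels(sample_ids, taxon_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    @classmethod
    def read(cls, path, sep: str | None = None) -> "CountTable":
        """Read a counts table (samples as rows, first column = sample labels)."""
        frame = _read_table(path, sep)
        return cls.from_frame(frame)

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="sample_id")


@dataclass(frozen=True)
class CompositionTable:
    """Samples x taxa proportions; each row sums to 1 and all entries are > 0."""

    values: np.ndarray
    sample_ids: list
    taxon_ids: list
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        sample_ids, taxon_ids = _check_labels(self.sample_ids, self.taxon_ids)
        if values.shape != (len(sample_ids), len(taxon_ids)):
            raise ValueError("label lengths do not match table shape")
        if np.any(values <= 0):
            raise ValueError("proportions must be strictly positive")
        rowsums = values.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-10):
            raise ValueError("proportion rows must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass(frozen=True)
class LogRatioTable:
    """Samples x (S-1) log-ratio coordinates relative to ``reference_taxon``.

    ``taxon_ids`` lists the S-1 non-reference taxa, in the order of the
    columns; the reference itself is carried separately.
    """

    values: np.ndarray
    sample_ids: list
    taxon_ids: list
    reference_taxon: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        sample_ids, taxon_ids = _check_labels(self.sample_ids, self.taxon_ids)
        if values.shape != (len(sample_ids), len(taxon_ids)):
            raise ValueError("label lengths do not match table shape")
        if self.reference_taxon in taxon_ids:
            raise ValueError("reference taxon must not appear among the log-ratio columns")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_ids", taxon_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def write(self, path, sep: str = "\t") -> None:
        """Write the table as TSV; the reference taxon goes in a sidecar ``.meta.json``."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, index_label="sample_id")
        meta = {"reference_taxon": self.reference_taxon}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def counts_to_proportions(counts: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> CompositionTable:
    """Estimate proportions ``rho[i, s] = (z[i, s] + pc) / sum_s' (z[i, s'] + pc)``.

    The pseudocount is added to every cell (not only zero cells) so the
    adjustment is exchangeable across taxa.  A pseudocount of 0 is only legal
    when no count is zero.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    z = counts.values.astype(float)
    if pseudocount == 0 and np.any(z == 0):
        i, s = np.argwhere(z == 0)[0]
        raise ValueError(
            f"zero count for sample {counts.sample_ids[i]!r}, taxon {counts.taxon_ids[s]!r}; "
            "a positive pseudocount is required"
        )
    adj = z + pseudocount
    rho = adj / adj.sum(axis=1, keepdims=True)
    return CompositionTable(rho, counts.sample_ids, counts.taxon_ids, pseudocount=pseudocount)


def log_ratio_transform(comp: CompositionTable, reference_taxon: str | None = None) -> LogRatioTable:
    """Map proportions to ``y[i, s] = log(rho[i, s] / rho[i, ref])``.

    The default reference is the last taxon column.  Non-reference columns
    keep their input order.
    """
    if reference_taxon is None:
        reference_taxon = comp.taxon_ids[-1]
    if reference_taxon not in comp.taxon_ids:
        raise KeyError(f"reference taxon {reference_taxon!r} not in table")
    ref_idx = comp.taxon_ids.index(reference_taxon)
    keep = [j for j in range(len(comp.taxon_ids)) if j != ref_idx]
    log_rho = np.log(comp.values)
    y = log_rho[:, keep] - log_rho[:, [ref_idx]]
    return LogRatioTable(
        y,
        comp.sample_ids,
        [comp.taxon_ids[j] for j in keep],
        reference_taxon,
    )


def inverse_log_ratio(y: LogRatioTable) -> CompositionTable:
    """Recover proportions from log-ratios.

    Uses ``rho_ref = 1 / (1 + sum_s exp(y_s))`` and ``rho_s = rho_ref * exp(y_s)``,
    evaluated through log-sum-exp so arbitrarily large finite coordinates never
    produce NaN.  The reference taxon is appended as the last column.
    """
    vals = np.asarray(y.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("log-ratio values must be finite")
    n = vals.shape[0]
    # log rho = [y, 0] - logsumexp([y, 0]) rowwise
    aug = np.concatenate([vals, np.zeros((n, 1))], axis=1)
    log_rho = aug - logsumexp(aug, axis=1, keepdims=True)
    rho = np.exp(log_rho)
    # keep strict positivity when a coordinate underflows (|y| ~ 700+)
    rho = np.maximum(rho, np.finfo(float).tiny)
    rho /= rho.sum(axis=1, keepdims=True)  # remove residual rounding
    return CompositionTable(
        rho,
        y.sample_ids,
        list(y.taxon_ids) + [y.reference_taxon],
        pseudocount=0.0,
    )
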