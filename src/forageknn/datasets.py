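"""Synthetic vocal-feature tables and CSV I/O.

Sustained-phonation datasets used in voice-based Parkinson's screening are
small two-class tables: a few hundred recordings, 20-30 real-valued
acoustic measurements (fundamental-frequency statistics, jitter and shimmer
perturbation families, noise ratios, nonlinear dynamics measures) and a
binary disease label with a strong class imbalance (about three quarters of
recordings come from patients).  The generator here emulates exactly that
shape — class-conditional Gaussian features, equicorrelated blocks standing
in for the highly collinear jitter/shimmer families, a controllable
standardized mean shift on the informative features — so every pipeline
stage is testable without downloading the originals.

Two CSV dialects are supported:

* ``oxford``  — a leading ``name`` column, 22 named feature columns and a
  0/1 ``status`` label column;
* ``istanbul`` — 26 feature columns plus a final label column;
* ``generic`` — any numeric table whose last column is the label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ContractError, FormatError

__all__ = [
    "DatasetSpec",
    "MinMaxScaler",
    "generate",
    "oxford_like",
    "istanbul_like",
    "read_feature_csv",
    "write_feature_csv",
    "scale_minmax",
    "OXFORD_FEATURES",
]

OXFORD_FEATURES = [
    "MDVP:Fo(Hz)", "MDVP:Fhi(Hz)", "MDVP:Flo(Hz)", "MDVP:Jitter(%)",
    "MDVP:Jitter(Abs)", "MDVP:RAP", "MDVP:PPQ", "Jitter:DDP",
    "MDVP:Shimmer", "MDVP:Shimmer(dB)", "Shimmer:APQ3", "Shimmer:APQ5",
    "MDVP:APQ", "Shimmer:DDA", "NHR", "HNR", "RPDE", "D2", "DFA",
    "spread1", "spread2", "PPE",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of the two-class Gaussian feature generator.

    ``effect_size`` is the standardized mean shift applied to each
    informative feature in the positive class (features have unit marginal
    variance, so it is directly a Cohen's d per feature).
    ``block_correlation`` is the within-block equicorrelation emulating the
    jitter/shimmer measurement families.
    """

    n_positive: int = 147
    n_negative: int = 48
    n_features: int = 22
    effect_size: float = 1.0
    n_informative: int | None = None
    block_correlation: float = 0.6
    block_size: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.n_positive < 1 or self.n_negative < 1 or self.n_features < 1:
            raise ContractError("counts must be positive")
        ninf = self.n_features if self.n_informative is None else self.n_informative
        if not 0 <= ninf <= self.n_features:
            raise ContractError("n_informative must be in [0, n_features]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ContractError("block_correlation must lie in [0, 1)")
        if self.block_size < 1:
            raise ContractError("block_size must be >= 1")

    @property
    def informative(self) -> int:
        return self.n_features if self.n_informative is None else self.n_informative


def oxford_like(**overrides) -> DatasetSpec:
    """Preset emulating the Oxford-style table: 147 PD + 48 control
    recordings, 22 features."""
    spec = DatasetSpec(n_positive=147, n_negative=48, n_features=22,
                       n_informative=10, block_size=5)
    return replace(spec, **overrides) if overrides else spec


def istanbul_like(**overrides) -> DatasetSpec:
    """Preset emulating the Istanbul-style table: 192 PD + 96 control
    sustained-vowel recordings, 26 features."""
    spec = DatasetSpec(n_positive=192, n_negative=96, n_features=26,
                       n_informative=10, block_size=5)
    return replace(spec, **overrides) if overrides else spec


def generate(spec: DatasetSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a feature table and 0/1 labels from the generator.

    Features are standard Gaussians grouped into consecutive equicorrelated
    blocks of ``block_size`` (correlation ``block_correlation`` within a
    block, independent across blocks); the first ``n_informative`` features
    gain a ``+effect_size`` mean shift in the positive (label 1) class.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positive + spec.n_negative
    p = spec.n_features
    rho = spec.block_correlation

    # equicorrelated block: x = sqrt(rho) * shared + sqrt(1 - rho) * own
    X = np.empty((n, p))
    start = 0
    while start < p:
        width = min(spec.block_size, p - start)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        X[:, start : start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        start += width

    y = np.concatenate([np.ones(spec.n_positive, dtype=int),
                        np.zeros(spec.n_negative, dtype=int)])
    X[y == 1, : spec.informative] += spec.effect_size

    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    if p == 22:
        cols = list(OXFORD_FEATURES)
    else:
        cols = [f"S{i + 1}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


def _numeric_or_raise(df: pd.DataFrame, path) -> np.ndarray:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.any().any():
        r = int(np.nonzero(bad.to_numpy())[0][0])
        c = bad.columns[int(np.nonzero(bad.to_numpy()[r])[0][0])]
        raise FormatError(
            f"{path}: non-numeric value {df.iloc[r][c]!r} in row {r}, column {c!r}"
        )
    if coerced.isna().any().any():
        r, c = np.nonzero(coerced.isna().to_numpy())
        raise FormatError(f"{path}: missing value in row {int(r[0])}, "
                          f"column {coerced.columns[int(c[0])]!r}")
    return coerced.to_numpy(dtype=float)


def read_feature_csv(path, dialect: str = "generic") -> tuple[pd.DataFrame, np.ndarray]:
    """Read a feature table and labels from CSV.

    ``oxford``: drops the ``name`` column, label from ``status``;
    ``istanbul``/``generic``: the last column is the label.
    """
    if dialect not in ("oxford", "istanbul", "generic"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if dialect == "oxford":
        if "status" not in df.columns:
            raise FormatError(f"{path}: oxford dialect requires a 'status' column")
        labels = df["status"]
        feats = df.drop(columns=["status"])
        if "name" in feats.columns:
            feats = feats.drop(columns=["name"])
    else:
        if df.shape[1] < 2:
            raise FormatError(f"{path}: need at least one feature and a label column")
        labels = df.iloc[:, -1]
        feats = df.iloc[:, :-1]
    y = pd.to_numeric(labels, errors="coerce")
    if y.isna().any():
        r = int(y.isna().to_numpy().nonzero()[0][0])
        raise FormatError(f"{path}: non-numeric label in row {r}")
    X = _numeric_or_raise(feats, path)
    return pd.DataFrame(X, columns=[str(c) for c in feats.columns]), y.to_numpy(dtype=int)


def write_feature_csv(path, features, labels, dialect: str = "generic",
                      names=None) -> None:
    """Write a feature table and labels in one of the supported dialects.

    Values are written with full double precision, so a write -> read
    round trip is lossless.
    """
    X = pd.DataFrame(features).copy()
    y = np.asarray(labels)
    if dialect == "oxford":
        if X.shape[1] != len(OXFORD_FEATURES):
            raise FormatError(
                f"oxford dialect requires {len(OXFORD_FEATURES)} features, "
                f"got {X.shape[1]}"
            )
        X.columns = OXFORD_FEATURES
        if names is None:
            names = [f"synthetic_R{i:04d}" for i in range(len(X))]
        out = pd.concat(
            [pd.Series(names, name="name"), X.reset_index(drop=True),
             pd.Series(y, name="status")],
            axis=1,
        )
    elif dialect == "istanbul":
        X.columns = [f"S{i + 1}" for i in range(X.shape[1])]
        out = X.reset_index(drop=True)
        out["label"] = y
    elif dialect == "generic":
        out = X.reset_index(drop=True)
        out["label"] = y
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    out.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class MinMaxScaler:
    """Per-feature affine map fitted on a training table."""

    min_: np.ndarray
    range_: np.ndarray  # zero for constant features

    def transform(self, table) -> np.ndarray:
        X = np.asarray(table, dtype=float)
        safe = np.where(self.range_ > 0, self.range_, 1.0)
        out = (X - self.min_) / safe
        return np.where(self.range_ > 0, out, 0.0)


def scale_minmax(train_table, *apply_tables):
    """Fit a [0, 1] min-max scaling on the training table and apply it.

    Training columns span exactly [0, 1] (constant columns map to 0).
    Applied tables use the *training* minima/ranges — they may exceed
    [0, 1] and are deliberately not clipped, so no information from the
    held-out data leaks into the transform.

    Returns ``(scaled_train, *scaled_applies, scaler)``.
    """
    X = np.asarray(train_table, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ContractError("train table must be non-empty and 2-D")
    scaler = MinMaxScaler(min_=X.min(axis=0), range_=X.max(axis=0) - X.min(axis=0))
    out = [scaler.transform(X)]
    out.extend(scaler.transform(t) for t in apply_tables)
    out.append(scaler)
    return tuple(out)
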