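"""Survival datasets: container, file I/O, filtering and splitting.

External file formats are plain TSV/CSV:

* survival table — columns ``id``, ``time``, ``status`` (0/1);
* covariate matrix — first column ``id``, remaining columns one feature each,
  header row required;
* secondary-data table — either columns ``feature``, ``sigma`` or a full
  samples x features matrix from which per-feature standard deviations are
  taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SurvivalDataset:
    """Right-censored survival data with a covariate matrix."""

    ids: np.ndarray
    times: np.ndarray
    status: np.ndarray
    X: np.ndarray
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.ids = np.asarray(self.ids)
        n = len(self.times)
        if np.any(self.times < 0):
            raise ValueError("survival times must be nonnegative")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be coded strictly as 0/1")
        if np.isnan(self.X).any():
            raise ValueError("covariate matrix contains missing values")
        if self.X.shape[0] != n or len(self.ids) != n:
            raise ValueError("times, status, ids and X rows must align")
        if not self.feature_names:
            self.feature_names = [f"x{i + 1}" for i in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows) -> "SurvivalDataset":
        rows = np.asarray(rows)
        return SurvivalDataset(ids=self.ids[rows], times=self.times[rows],
                               status=self.status[rows], X=self.X[rows],
                               feature_names=list(self.feature_names))

    def standardized(self) -> "SurvivalDataset":
        """Per-feature mean 0 / sd 1 copy (constant features left centred)."""
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        return SurvivalDataset(ids=self.ids, times=self.times,
                               status=self.status, X=(self.X - mu) / sd,
                               feature_names=list(self.feature_names))


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def load_dataset(cov_path, surv_path, standardize: bool = True) -> SurvivalDataset:
    """Load and align a covariate matrix with a survival table by ``id``."""
    cov = _read_table(cov_path)
    surv = _read_table(surv_path)
    for col in ("id", "time", "status"):
        if col not in surv.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    cov = cov.rename(columns={cov.columns[0]: "id"})
    cov_ids = set(cov["id"])
    surv_ids = set(surv["id"])
    missing = cov_ids.symmetric_difference(surv_ids)
    if missing:
        raise ValueError(
            "ids present in only one file: " + ", ".join(map(str, sorted(missing)[:5])))
    cov = cov.set_index("id").loc[surv["id"]]
    Xdf = cov.apply(pd.to_numeric, errors="coerce")
    if Xdf.isna().any().any():
        bad = Xdf.columns[Xdf.isna().any()].tolist()
        raise ValueError(f"non-numeric or missing covariate cells in: {bad}")
    ds = SurvivalDataset(ids=surv["id"].to_numpy(),
                         times=surv["time"].to_numpy(dtype=float),
                         status=surv["status"].to_numpy(),
                         X=Xdf.to_numpy(dtype=float),
                         feature_names=list(Xdf.columns))
    return ds.standardized() if standardize else ds


def write_dataset(ds: SurvivalDataset, cov_path, surv_path) -> None:
    """Write the covariate matrix and survival table as TSV."""
    pd.DataFrame(ds.X, columns=ds.feature_names).assign(id=ds.ids) \
        .set_index("id").reset_index() \
        .to_csv(cov_path, sep="\t", index=False)
    pd.DataFrame({"id": ds.ids, "time": ds.times, "status": ds.status}) \
        .to_csv(surv_path, sep="\t", index=False)


def load_secondary_sigma(path, feature_names=None) -> np.ndarray:
    """Per-feature dispersion from a secondary-data file.

    Accepts a two-column ``feature``/``sigma`` table or a full matrix whose
    first column is ``id`` (per-feature standard deviations across samples
    are then computed).
    """
    df = _read_table(path)
    cols = [c.lower() for c in df.columns]
    if "sigma" in cols:
        df.columns = cols
        df = df.set_index("feature")
        if feature_names is not None:
            df = df.loc[list(feature_names)]
        return df["sigma"].to_numpy(dtype=float)
    df = df.rename(columns={df.columns[0]: "id"}).set_index("id")
    if feature_names is not None:
        df = df[list(feature_names)]
    return df.std(axis=0, ddof=1).to_numpy(dtype=float)


def select_top_variance(X, n_keep: int):
    """Keep the n_keep highest-variance features (ties -> lower index).

    Returns ``(kept_column_indices, variance_fraction)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if n_keep > p:
        raise ValueError("cannot keep more features than exist")
    var = X.var(axis=0, ddof=1)
    order = np.argsort(-var, kind="stable")
    kept = np.sort(order[:n_keep])
    frac = float(var[kept].sum() / var.sum()) if var.sum() > 0 else 0.0
    return kept, frac


def train_test_split(ds: SurvivalDataset, ratio: float = 2 / 3,
                     seed: int = 0):
    """Seeded random split; train gets ``ceil(n * ratio)`` subjects."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    n = ds.n
    n_train = int(np.ceil(n * ratio))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return ds.subset(np.sort(perm[:n_train])), ds.subset(np.sort(perm[n_train:]))
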