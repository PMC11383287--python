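"""Initial-state PCA: relating Gen-1 mother states to progeny division counts.

The cell-by-species matrix of Generation-1 initial conditions is z-scored
column-wise and decomposed with PCA; drug-treated populations are projected
onto the components learned from control data using the control means and
standard deviations (never re-fit).  Constant columns are dropped before
scaling and recorded.  Component signs follow the convention that the
largest-magnitude loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .lineage import progeny_division_count


@dataclass
class StateMatrix:
    """Cells x species matrix of Gen-1 initial concentrations."""

    values: np.ndarray
    row_ids: list
    columns: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("state matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("matrix shape does not match row/column ids")
        if not np.isfinite(self.values).all():
            raise ValueError("state matrix contains missing entries")

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.columns)


@dataclass
class PcaTransform:
    """Frozen standardization + orthonormal components of a control fit."""

    mean: np.ndarray
    std: np.ndarray
    components: np.ndarray          # (n_components, n_kept_columns)
    explained_variance_ratio: np.ndarray
    columns: list                   # kept columns, in order
    dropped_columns: list = field(default_factory=list)

    @property
    def n_components(self):
        return self.components.shape[0]


def initial_state_matrix(result):
    """Gen-1 mothers' initial states, paired with progeny division counts."""
    recs = sorted(result.generation(1), key=lambda r: r.index)
    if not recs:
        raise ValueError("result has no Generation-1 records")
    if any(r.initial_state is None for r in recs):
        raise ValueError("initial states were not stored for this result")
    model_species = list(result.config.get("species", []))
    if not model_species:
        model_species = [f"s{i}" for i in range(len(recs[0].initial_state))]
    matrix = StateMatrix(
        values=np.stack([r.initial_state for r in recs]),
        row_ids=[r.cell_id for r in recs],
        columns=model_species,
    )
    counts = np.array([progeny_division_count(result, r.cell_id) for r in recs])
    return matrix, counts


def fit_pca(matrix, n_components=None):
    """Standardized PCA of a state matrix.

    Returns (transform, scores).  Columns are z-scored; zero-variance columns
    are dropped and listed in the transform; components come from the
    covariance eigenstructure of the standardized matrix (via sklearn's PCA,
    as in the original analysis).
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    std0 = X.std(axis=0)
    keep = std0 > 0
    if keep.sum() < 1:
        raise ValueError("degenerate input: all columns are constant")
    kept_cols = [c for c, k in zip(matrix.columns, keep) if k]
    dropped = [c for c, k in zip(matrix.columns, keep) if not k]
    Xk = X[:, keep]

    scaler = StandardScaler().fit(Xk)
    Z = scaler.transform(Xk)
    if n_components is None:
        n_components = min(Z.shape)
    pca = PCA(n_components=n_components, svd_solver="full").fit(Z)
    components = pca.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
    transform = PcaTransform(
        mean=scaler.mean_.copy(),
        std=np.sqrt(scaler.var_),
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        columns=kept_cols,
        dropped_columns=dropped,
    )
    scores = Z @ components.T
    return transform, scores


def project(transform, matrix):
    """Scores of new data in the control component space.

    Standardization uses the CONTROL means and standard deviations; the
    transform is never re-fit.  Columns must match the transform's kept
    columns (dropped columns are removed automatically if present).
    """
    cols = list(matrix.columns)
    if cols != transform.columns:
        if set(transform.columns) - set(cols):
            missing = sorted(set(transform.columns) - set(cols))
            raise ValueError(f"new matrix is missing columns: {missing}")
        idx = [cols.index(c) for c in transform.columns]
        X = matrix.values[:, idx]
    else:
        X = matrix.values
    Z = (X - transform.mean) / transform.std
    return Z @ transform.components.T


def top_loadings(transform, component=2, k=20):
    """The ``k`` species with the largest |loading| on a component (1-based).

    Defaults pick the top 20 loadings of PC2, the component that stratified
    division phenotypes in the original analysis.  Signed loadings are
    returned, ranked by magnitude.
    """
    if not (1 <= component <= transform.n_components):
        raise ValueError(
            f"component {component} outside fitted range "
            f"1..{transform.n_components}")
    load = transform.components[component - 1]
    if k > len(load):
        import warnings
        warnings.warn(f"k={k} exceeds {len(load)} species; truncating")
        k = len(load)
    order = np.argsort(-np.abs(load))[:k]
    return pd.DataFrame({
        "species": [transform.columns[i] for i in order],
        "loading": load[order],
    })


def inverse_transform(transform, scores):
    """Standardized-space reconstruction from scores (all components kept)."""
    return scores @ transform.components


def component_correlations(scores, response):
    """|Pearson r| of each component's scores against a response vector."""
    response = np.asarray(response, dtype=float)
    out = []
    for i in range(scores.shape[1]):
        s = scores[:, i]
        if s.std() == 0 or response.std() == 0:
            out.append(0.0)
        else:
            out.append(float(np.corrcoef(s, response)[0, 1]))
    return np.array(out)
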