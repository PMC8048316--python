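"""Nonlinear PCA on binarized variant carriage, computed as multiple
correspondence analysis (MCA) of the complete disjunctive indicator matrix.

Each variant contributes two indicator columns (carrier / non-carrier of the
alt allele).  The decomposition is the correspondence analysis of that
matrix: SVD of the standardized residuals of the correspondence matrix, with
principal inertias equal to the squared singular values.  For complete
disjunctive coding the total inertia is (J / q) - 1 where J is the number of
indicator columns and q the number of variables.  Inertia proportions are
reported raw (no Benzecri / Greenacre correction).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genotypes import CohortGenotypes


@dataclasses.dataclass
class IndicatorMatrix:
    data: pd.DataFrame  # rows: samples; columns: <rsid>=carrier / <rsid>=non
    q: int  # number of original variables
    dropped_variants: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class MCAResult:
    eigenvalues: np.ndarray  # principal inertias, nonincreasing
    inertia_proportions: np.ndarray
    row_scores: pd.DataFrame  # samples x components, principal coordinates
    column_loadings: pd.DataFrame  # indicator columns x components
    total_inertia: float
    selected_k: int


def binarize(cohort: CohortGenotypes, variants: list[str] | None = None) -> IndicatorMatrix:
    """Complete disjunctive coding of alt-allele carrier status.

    carrier = dosage >= 1.  Monomorphic variants (no variation in carrier
    status) are dropped with a warning; samples with every call missing are
    excluded.  A missing individual call codes as non-carrier.
    """
    if variants is None:
        variants = sorted({rs for s in cohort for rs in s.calls})
    rows = []
    index = []
    for s in cohort:
        if all(s.dosage(rs) is None for rs in variants):
            warnings.warn(f"sample {s.sample_id} has no calls; excluded from MCA")
            continue
        rows.append([1 if (s.dosage(rs) or 0) >= 1 else 0 for rs in variants])
        index.append(s.sample_id)
    carrier = pd.DataFrame(rows, index=index, columns=variants)

    dropped = tuple(rs for rs in variants if carrier[rs].nunique() < 2)
    if dropped:
        warnings.warn(f"monomorphic variants dropped from MCA: {', '.join(dropped)}")
        carrier = carrier.drop(columns=list(dropped))

    blocks = {}
    for rs in carrier.columns:
        blocks[f"{rs}=carrier"] = carrier[rs]
        blocks[f"{rs}=non"] = 1 - carrier[rs]
    data = pd.DataFrame(blocks, index=carrier.index)
    return IndicatorMatrix(data=data, q=carrier.shape[1], dropped_variants=dropped)


def mca_fit(m: IndicatorMatrix, k: int | None = None) -> MCAResult:
    """Correspondence-analysis decomposition of an indicator matrix."""
    z = m.data.to_numpy(dtype=float)
    if z.shape[0] < 2 or m.q < 2:
        raise ValueError("MCA needs at least 2 samples and 2 variables")
    n = z.sum()
    p = z / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    # standardized residuals; the trivial (constant) dimension is removed by
    # the centering and shows up as a ~zero singular value discarded below
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)

    keep = sv > 1e-12
    u, sv, vt = u[:, keep], sv[keep], vt[keep]
    eig = sv**2
    total = float(m.n_columns / m.q - 1)

    row_scores = (u * sv) / np.sqrt(r)[:, None]
    col_loadings = (vt.T * sv) / np.sqrt(c)[:, None]
    # sign convention: orient each axis so its largest-|loading| is positive
    for j in range(col_loadings.shape[1]):
        i = np.argmax(np.abs(col_loadings[:, j]))
        if col_loadings[i, j] < 0:
            col_loadings[:, j] *= -1
            row_scores[:, j] *= -1

    comp_names = [f"PC{i + 1}" for i in range(len(eig))]
    result = MCAResult(
        eigenvalues=eig,
        inertia_proportions=eig / eig.sum(),
        row_scores=pd.DataFrame(row_scores, index=m.data.index, columns=comp_names),
        column_loadings=pd.DataFrame(col_loadings, index=m.data.columns, columns=comp_names),
        total_inertia=total,
        selected_k=0,
    )
    result.selected_k = k if k is not None else select_components(eig)
    return result


def select_components(eigenvalues: np.ndarray | list[float]) -> int:
    """Scree elbow: the largest k before the maximal drop in successive
    eigenvalue differences."""
    eig = np.asarray(eigenvalues, dtype=float)
    if len(eig) < 3:
        return len(eig)
    diffs = eig[:-1] - eig[1:]
    if np.allclose(diffs, 0):
        warnings.warn("flat scree (all eigenvalues equal); selecting k=1")
        return 1
    return int(np.argmax(diffs)) + 1


def flag_outliers(
    result: MCAResult, components: list[int] | range | None = None, k: float = 6.0
) -> list[str]:
    """Samples with extreme scores on the given components (1-based), flagged
    when beyond median +/- k * MAD, sorted by decreasing extremity."""
    if components is None:
        components = range(1, result.selected_k + 1)
    extremity: dict[str, float] = {}
    for comp in components:
        col = result.row_scores[f"PC{comp}"]
        med = col.median()
        mad = (col - med).abs().median()
        if mad == 0 or not np.isfinite(k):
            continue
        z = (col - med).abs() / mad
        for sid, val in z[z > k].items():
            extremity[sid] = max(extremity.get(sid, 0.0), float(val))
    return sorted(extremity, key=lambda sid: -extremity[sid])


def scree_plot(result: MCAResult, path: str) -> None:
    """Write a scree plot of the principal inertias."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(1, len(result.eigenvalues) + 1)
    ax.plot(x, result.eigenvalues, "o-")
    ax.axvline(result.selected_k + 0.5, color="grey", ls="--", lw=1)
    ax.set_xlabel("component")
    ax.set_ylabel("principal inertia")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
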