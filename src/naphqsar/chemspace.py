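"""Descriptor-space PCA with the pipeline's preprocessing conventions.

Before decomposition, columns that are constant or nearly constant
(standard deviation below 1e-4) or that contain missing entries are
dropped; the remaining matrix is centered and, by default, standardized
(the descriptor pools mix scales over several orders of magnitude).
A small open-source descriptor block (counts, size, polarity, Ro5 terms,
estimated logP) is provided for exercising the chemical-space analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.decomposition import PCA

SD_THRESHOLD = 1e-4


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # n x k, columns PC1..PCk
    loadings: pd.DataFrame  # p x k
    explained_variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    preprocessing: dict


def preprocess_descriptors(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop near-constant (SD < 1e-4) and missing-value columns, with a log."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    has_na = matrix.columns[matrix.isna().any()].tolist()
    kept = matrix.drop(columns=has_na)
    sd = kept.std(axis=0, ddof=1)
    near_constant = sd.index[sd < SD_THRESHOLD].tolist()
    kept = kept.drop(columns=near_constant)
    if kept.shape[1] == 0:
        raise ValueError("preprocessing removed every column")
    log = {
        "n_columns_in": matrix.shape[1],
        "n_columns_out": kept.shape[1],
        "dropped_missing": has_na,
        "dropped_near_constant": near_constant,
    }
    return kept, log


def run_pca(
    matrix: pd.DataFrame, standardize: bool = True, n_components: int | None = None
) -> PCAResult:
    """Centered (and standardized, by default) PCA with variance reporting."""
    filtered, log = preprocess_descriptors(matrix)
    X = filtered.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        X = X / X.std(axis=0, ddof=1)
    k = min(X.shape) if n_components is None else min(n_components, *X.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    if pca.explained_variance_[0] <= 1e-30:
        raise ValueError("matrix has rank 0 after preprocessing")
    pct = 100.0 * pca.explained_variance_ratio_
    names = [f"PC{i + 1}" for i in range(k)]
    log.update(centering=True, standardized=standardize)
    return PCAResult(
        scores=pd.DataFrame(scores, index=filtered.index, columns=names),
        loadings=pd.DataFrame(pca.components_.T, index=filtered.columns, columns=names),
        explained_variance_pct=pct,
        cumulative_pct=np.cumsum(pct),
        preprocessing=log,
    )


def _ro5_violations(mol: Chem.Mol) -> int:
    return sum(
        [
            Descriptors.MolWt(mol) > 500,
            Crippen.MolLogP(mol) > 5,
            Lipinski.NumHDonors(mol) > 5,
            Lipinski.NumHAcceptors(mol) > 10,
        ]
    )


def compute_open_descriptors(smiles_by_id: dict[str, str]) -> pd.DataFrame:
    """Open-source 2D descriptor block (RDKit) for the chemical-space PCA.

    Rows that fail to parse are excluded with a warning.
    """
    rows = {}
    for cid, smi in smiles_by_id.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            warnings.warn(f"SMILES of {cid!r} failed to parse; row excluded", stacklevel=2)
            continue
        rows[cid] = {
            "heavy_atoms": mol.GetNumHeavyAtoms(),
            "rings": rdMolDescriptors.CalcNumRings(mol),
            "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
            "rotatable_bonds": Lipinski.NumRotatableBonds(mol),
            "h_donors": Lipinski.NumHDonors(mol),
            "h_acceptors": Lipinski.NumHAcceptors(mol),
            "mol_weight": Descriptors.MolWt(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "clogp": Crippen.MolLogP(mol),
            "mol_refractivity": Crippen.MolMR(mol),
            "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
            "halogens": sum(a.GetSymbol() in ("F", "Cl", "Br", "I") for a in mol.GetAtoms()),
            "ro5_violations": _ro5_violations(mol),
        }
    if not rows:
        raise ValueError("no SMILES parsed")
    return pd.DataFrame.from_dict(rows, orient="index")
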