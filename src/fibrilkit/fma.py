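"""Principal component and functional mode analysis of fibril motion.

PCA diagonalises the covariance of superposed Cα coordinates; functional
mode analysis (FMA) then models a scalar observable — here typically the
fibril order parameter — as a linear function of the leading principal
components, fitted on a model-building subset of frames and
cross-validated on a disjoint subset.  Collapsing the fitted
coefficients back onto the PCA eigenvectors yields a single unit-norm
collective vector, the ensemble-weighted maximally correlated motion
(ewMCM): the one collective coordinate whose motion best explains the
observable's fluctuation.

The API follows the model/results pattern:

>>> pca = fit_pca(traj)                       # doctest: +SKIP
>>> fma = FunctionalModeAnalysis(pca, ordp.values, split="half")
>>> res = fma.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StructureError, Trajectory
from .geometry import ResidueProfile, superpose_trajectory

__all__ = [
    "PcaModel",
    "FMAResults",
    "FunctionalModeAnalysis",
    "fit_pca",
    "fit_fma",
    "ewmcm_trajectory",
    "rmsf_on_ewmcm",
]


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PcaModel:
    """PCA of superposed coordinates.

    ``components`` rows are orthonormal modes over the flattened
    selection coordinates (3·N_sel), sorted by descending eigenvalue
    (nm²); ``projections`` holds every frame's coordinates projected on
    every mode.
    """

    mean: np.ndarray                 # (3N,)
    components: np.ndarray           # (n_modes, 3N)
    eigenvalues: np.ndarray          # (n_modes,), nm², descending
    projections: np.ndarray          # (n_frames, n_modes)
    selection: np.ndarray            # atom indices the PCA was built on
    trajectory: Trajectory | None = None
    zero_variance: bool = False

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_frames(self) -> int:
        return self.projections.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot


def fit_pca(traj: Trajectory, selection: np.ndarray | None = None) -> PcaModel:
    """PCA of the (superposed) selected coordinates; default selection: Cα.

    Frames are Cα-superposed onto the reference internally; the sample
    covariance of the flattened selection coordinates is diagonalised
    and modes are sorted by descending eigenvalue.
    """
    if traj.n_frames < 2:
        raise StructureError("PCA needs at least 2 frames")
    if selection is None:
        selection = traj.topology.calpha_indices()
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    coords = superpose_trajectory(traj, fit_selection=sel)[:, sel, :]
    x = coords.reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD: eigenvalues of the sample covariance are s² / (n−1)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (traj.n_frames - 1)
    projections = u * s
    zero = bool(np.allclose(eigenvalues, 0.0))
    return PcaModel(
        mean=mean,
        components=vt,
        eigenvalues=eigenvalues,
        projections=projections,
        selection=sel,
        trajectory=traj,
        zero_variance=zero,
    )


# ----------------------------------------------------------------------
# FMA
# ----------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _resolve_split(split, n_frames: int, seed: int | None) -> np.ndarray:
    """Boolean build mask over frames; the complement is validation."""
    if isinstance(split, str):
        if split == "half":
            mask = np.zeros(n_frames, dtype=bool)
            mask[: n_frames // 2] = True
            return mask
        if split == "random":
            rng = np.random.default_rng(0 if seed is None else seed)
            perm = rng.permutation(n_frames)
            mask = np.zeros(n_frames, dtype=bool)
            mask[perm[: n_frames // 2]] = True
            return mask
        raise ValueError(f"unknown split {split!r}")
    mask = np.asarray(split, dtype=bool)
    if mask.shape != (n_frames,):
        raise ValueError("split mask length must equal the frame count")
    if not mask.any() or mask.all():
        raise ValueError("both build and validation subsets must be non-empty")
    return mask


@dataclass
class FMAResults:
    """Fitted functional-mode model.

    ``ewmcm`` is the unit-norm collective vector (3·N_sel), oriented so
    that its motion correlates positively with the response.
    """

    model: "FunctionalModeAnalysis"
    n_modes_used: int
    coefficients: np.ndarray
    intercept: float
    ewmcm: np.ndarray
    pearson_build: float
    pearson_validation: float
    build_mask: np.ndarray

    def predict(self, projections: np.ndarray | None = None) -> np.ndarray:
        p = self.model.pca.projections if projections is None else projections
        return self.intercept + p[:, : self.n_modes_used] @ self.coefficients

    def ewmcm_projections(self) -> np.ndarray:
        """Projection of every frame's deviation from the mean onto ewMCM."""
        pca = self.model.pca
        # frame deviations in mode space → back onto ewMCM
        return pca.projections @ (pca.components @ self.ewmcm)

    def summary(self) -> str:
        ev = self.model.pca.explained_variance_ratio()[: self.n_modes_used].sum()
        lines = [
            "Functional Mode Analysis Results",
            "=" * 44,
            f"{'frames (build/validation)':34s}{int(self.build_mask.sum()):>4d}/"
            f"{int((~self.build_mask).sum()):<d}",
            f"{'PCA modes used':34s}{self.n_modes_used:>6d}",
            f"{'coord. variance covered':34s}{100 * ev:>9.2f}%",
            f"{'Pearson r (build)':34s}{self.pearson_build:>9.4f}",
            f"{'Pearson r (cross-validation)':34s}{self.pearson_validation:>9.4f}",
            "-" * 44,
            "leading mode coefficients:",
        ]
        for k, c in enumerate(self.coefficients[: min(5, len(self.coefficients))]):
            lines.append(f"  PC{k + 1:<3d} {c:>12.5f}")
        return "\n".join(lines)


class FunctionalModeAnalysis:
    """Linear model of a scalar response on leading PCA projections.

    Parameters
    ----------
    pca : PcaModel
    response : array-like, one value per frame (e.g. an ordP series).
    n_modes : retained mode count; default: smallest count explaining
        ≥90% of the coordinate variance, capped at build_frames // 10
        (and at least 1).
    split : "half" (first half builds, second half validates),
        "random" (seeded permutation), or an explicit boolean build mask.
    """

    VARIANCE_TARGET = 0.90

    def __init__(
        self,
        pca: PcaModel,
        response: np.ndarray,
        n_modes: int | None = None,
        split="half",
        seed: int | None = None,
    ) -> None:
        response = np.asarray(getattr(response, "values", response), dtype=float)
        if response.shape != (pca.n_frames,):
            raise ValueError("response length must equal the PCA frame count")
        self.pca = pca
        self.response = response
        self.build_mask = _resolve_split(split, pca.n_frames, seed)
        self.n_modes = self._choose_modes(n_modes)

    @classmethod
    def from_trajectory(
        cls, traj: Trajectory, response, selection=None, **kwargs
    ) -> "FunctionalModeAnalysis":
        return cls(fit_pca(traj, selection), response, **kwargs)

    def _choose_modes(self, n_modes: int | None) -> int:
        n_build = int(self.build_mask.sum())
        if n_modes is None:
            ratios = np.cumsum(self.pca.explained_variance_ratio())
            m = int(np.searchsorted(ratios, self.VARIANCE_TARGET) + 1)
            m = max(1, min(m, max(n_build // 10, 1), self.pca.n_modes))
        else:
            m = int(n_modes)
            if m < 1 or m > self.pca.n_modes:
                raise ValueError(f"n_modes must be in 1..{self.pca.n_modes}")
        if m > n_build - 2:
            raise ValueError(
                f"retaining {m} modes with only {n_build} build frames would "
                "over-fit; reduce n_modes or enlarge the build subset"
            )
        return m

    def fit(self) -> FMAResults:
        m = self.n_modes
        build = self.build_mask
        p_build = self.pca.projections[build, :m]
        y_build = self.response[build]
        design = np.column_stack([np.ones(len(y_build)), p_build])
        beta, *_ = np.linalg.lstsq(design, y_build, rcond=None)
        intercept, coefs = float(beta[0]), beta[1:]

        # ensemble weighting: each mode's coefficient is scaled by its
        # eigenvalue, i.e. by how much the ensemble actually moves along
        # it — this is what distinguishes the ewMCM from the bare
        # coefficient vector and keeps near-zero-variance modes from
        # dominating the collective vector.
        ewmcm = (coefs * self.pca.eigenvalues[:m]) @ self.pca.components[:m]
        norm = np.linalg.norm(ewmcm)
        if norm == 0:
            raise StructureError("all FMA coefficients vanish: no correlated motion")
        ewmcm = ewmcm / norm

        predicted = intercept + self.pca.projections[:, :m] @ coefs
        r_build = _pearson(predicted[build], self.response[build])
        r_val = _pearson(predicted[~build], self.response[~build])
        # orient ewMCM so motion along it correlates positively with response
        s = self.pca.projections @ (self.pca.components @ ewmcm)
        if _pearson(s, self.response) < 0:
            ewmcm = -ewmcm
        return FMAResults(
            model=self,
            n_modes_used=m,
            coefficients=coefs,
            intercept=intercept,
            ewmcm=ewmcm,
            pearson_build=r_build,
            pearson_validation=r_val,
            build_mask=build,
        )


def fit_fma(
    pca: PcaModel,
    response,
    m: int | None = None,
    split="half",
    seed: int | None = None,
) -> FMAResults:
    """Functional wrapper: fit an FMA model and return its results."""
    return FunctionalModeAnalysis(pca, response, n_modes=m, split=split, seed=seed).fit()


# ----------------------------------------------------------------------
# ewMCM trajectories and filtered fluctuation
# ----------------------------------------------------------------------

def ewmcm_trajectory(pca: PcaModel, results: FMAResults, n_steps: int) -> Trajectory:
    """Interpolated motion along ewMCM between the extreme ensemble frames.

    Returns a trajectory over the PCA selection atoms whose frames move
    the mean structure along ewMCM from the minimum to the maximum
    observed projection; the first/last frames are the two extremes.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    s = results.ewmcm_projections()
    amplitudes = np.linspace(s.min(), s.max(), n_steps)
    coords = (
        pca.mean[None, :] + amplitudes[:, None] * results.ewmcm[None, :]
    ).reshape(n_steps, -1, 3)
    if pca.trajectory is None:
        raise ValueError("PCA model does not reference a trajectory/topology")
    sub_top = pca.trajectory.topology.subset(
        np.isin(np.arange(pca.trajectory.topology.n_atoms), pca.selection)
    )
    return Trajectory(topology=sub_top, coordinates=coords, label="ewMCM")


def rmsf_on_ewmcm(pca: PcaModel, results: FMAResults) -> ResidueProfile:
    """Per-residue RMSF of the trajectory filtered on the ewMCM vector.

    Each frame's deviation from the mean is replaced by its orthogonal
    projection onto ewMCM; the per-atom RMSF of that filtered motion is
    |ewMCM_atom| · std(s) with s the per-frame ewMCM projection.
    Averaged per residue and across chains as in the unfiltered RMSF.
    """
    if pca.trajectory is None:
        raise ValueError("PCA model does not reference a trajectory/topology")
    s = results.ewmcm_projections()
    amp = float(np.sqrt(np.mean((s - s.mean()) ** 2)))
    per_atom = amp * np.linalg.norm(results.ewmcm.reshape(-1, 3), axis=1)

    top = pca.trajectory.topology
    sel = pca.selection
    res = top.residue_numbers
    per_chain = np.full((top.n_chains, len(res)), np.nan)
    sel_res = top.residue_number[sel]
    sel_chain = top.chain_id[sel]
    for ci, chain in enumerate(top.chain_order):
        for ri, r in enumerate(res):
            m = (sel_res == r) & (sel_chain == chain)
            if m.any():
                per_chain[ci, ri] = per_atom[m].mean()
    return ResidueProfile(
        residue_numbers=res,
        mean=np.nanmean(per_chain, axis=0),
        std=np.nanstd(per_chain, axis=0),
        per_chain=per_chain,
        quantity="RMSF (ewMCM-filtered)",
        units="nm",
    )
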