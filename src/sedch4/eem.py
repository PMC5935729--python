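"""Fluorescence EEM processing: inner-filter correction, nonnegative PARAFAC,
split-half validation, component matching and the relative phenol index.

An excitation-emission matrix (EEM) records fluorescence intensity over a
grid of excitation and emission wavelengths.  A collection of porewater
EEMs forms a three-way array (sample x excitation x emission) that PARAFAC
decomposes into additive fluorophore components:

    X[i, j, k] ~= sum_f  a[i, f] * b[j, f] * c[k, f]

with nonnegative sample scores ``a`` and spectral loadings ``b`` (excitation)
and ``c`` (emission).  The component whose spectrum matches the water-soluble
phenol leachate signature is combined with porewater DOC into a relative
phenol concentration index: (component score / total score) * DOC.

The trilinear fit is an alternating least squares in hierarchical
(column-wise) form: each factor column update is the exact nonnegative
minimizer given the others, so the residual sum of squares is non-increasing
across iterations.  Missing values (NaN, e.g. excised scatter bands) are
handled by expectation-style imputation with the current model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EEMCube",
    "ReferenceSpectra",
    "DEFAULT_REFERENCE",
    "ParafacModel",
    "ParafacResults",
    "SplitHalfReport",
    "ComponentAssignment",
    "inner_filter_correct",
    "excise_scatter",
    "split_half_validate",
    "match_components",
    "tucker_congruence",
    "phenol_index",
    "gaussian_profile",
]

EX_GRID_NM = np.arange(250, 451, 5, dtype=float)  # 41 points
EM_GRID_NM = np.arange(300, 601, 2, dtype=float)  # 151 points


@dataclass
class EEMCube:
    """A stack of sample EEMs with absorbance and DOC sidecars.

    ``data`` is (n_samples, n_excitation, n_emission).  ``absorbance`` holds
    per-sample absorbance spectra (dimensionless, 1 cm path length) on
    ``absorbance_nm``, a grid that must cover both the excitation and the
    emission ranges so the inner-filter correction can interpolate.
    """

    sample_ids: list[str]
    ex_nm: np.ndarray
    em_nm: np.ndarray
    data: np.ndarray
    absorbance_nm: np.ndarray | None = None
    absorbance: np.ndarray | None = None
    doc_mg_l: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ex_nm = np.asarray(self.ex_nm, dtype=float)
        self.em_nm = np.asarray(self.em_nm, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if np.any(np.diff(self.ex_nm) <= 0) or np.any(np.diff(self.em_nm) <= 0):
            raise ValueError("wavelength grids must be strictly increasing")
        if self.data.shape != (len(self.sample_ids), len(self.ex_nm), len(self.em_nm)):
            raise ValueError("data must be (n_samples, n_ex, n_em)")
        if np.any(np.isinf(self.data)):
            raise ValueError("intensities must be finite")
        if self.doc_mg_l is not None:
            self.doc_mg_l = np.asarray(self.doc_mg_l, dtype=float)
            if np.any(self.doc_mg_l < 0):
                raise ValueError("DOC must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx) -> "EEMCube":
        idx = np.asarray(idx)
        return EEMCube(
            sample_ids=[self.sample_ids[i] for i in idx],
            ex_nm=self.ex_nm,
            em_nm=self.em_nm,
            data=self.data[idx],
            absorbance_nm=self.absorbance_nm,
            absorbance=None if self.absorbance is None else self.absorbance[idx],
            doc_mg_l=None if self.doc_mg_l is None else self.doc_mg_l[idx],
        )


@dataclass(frozen=True)
class ReferenceSpectra:
    """Gaussian reference fluorophores: peak positions and widths in nm.

    Defaults describe the five components recurring in porewater dissolved
    organic matter: two humic-like components, tryptophan- and tyrosine-like
    protein components, and the protein-like component associated with leaf
    litter phenol leachates.
    """

    labels: tuple[str, ...] = (
        "humic-like-1",
        "humic-like-2",
        "tryptophan-like",
        "tyrosine-like",
        "phenol-leachate",
    )
    ex_peak_nm: tuple[float, ...] = (310.0, 345.0, 280.0, 270.0, 275.0)
    em_peak_nm: tuple[float, ...] = (414.0, 462.0, 354.0, 306.0, 318.0)
    ex_sigma_nm: float = 15.0
    em_sigma_nm: float = 25.0

    def __post_init__(self) -> None:
        if self.ex_sigma_nm <= 0 or self.em_sigma_nm <= 0:
            raise ValueError("spectral widths must be positive")
        for p in self.ex_peak_nm:
            if not (EX_GRID_NM[0] <= p <= EX_GRID_NM[-1]):
                raise ValueError(f"excitation peak {p} nm off the 250-450 nm grid")
        for p in self.em_peak_nm:
            if not (EM_GRID_NM[0] <= p <= EM_GRID_NM[-1]):
                raise ValueError(f"emission peak {p} nm off the 300-600 nm grid")

    @property
    def n_components(self) -> int:
        return len(self.labels)

    def profiles(self, ex_nm: np.ndarray, em_nm: np.ndarray):
        """Gaussian excitation / emission profiles on the given grids."""
        ex = np.column_stack(
            [gaussian_profile(ex_nm, p, self.ex_sigma_nm) for p in self.ex_peak_nm]
        )
        em = np.column_stack(
            [gaussian_profile(em_nm, p, self.em_sigma_nm) for p in self.em_peak_nm]
        )
        return ex, em


#: The five-fluorophore reference set used throughout the pipeline.
DEFAULT_REFERENCE = ReferenceSpectra()


def gaussian_profile(grid: np.ndarray, peak_nm: float, sigma_nm: float) -> np.ndarray:
    return np.exp(-0.5 * ((np.asarray(grid, float) - peak_nm) / sigma_nm) ** 2)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def inner_filter_correct(cube: EEMCube, max_absorbance: float = 1.5):
    """Correct measured EEMs for primary and secondary inner-filter effects.

    The attenuation of fluorescence by the sample's own absorbance at the
    excitation and emission wavelengths is undone multiplicatively:

        corrected = raw * 10 ** ((A(ex) + A(em)) / 2)

    assuming a 1 cm cuvette path length.  Absorbance is interpolated
    linearly onto the EEM grids.  Samples whose maximum absorbance exceeds
    ``max_absorbance`` are beyond the validity of the correction and are
    returned in the flag list (still corrected).

    Returns
    -------
    (EEMCube, list[str]) : corrected cube and flagged sample ids.
    """
    if cube.absorbance is None or cube.absorbance_nm is None:
        raise ValueError("absorbance spectra are required for inner-filter correction")
    wl = np.asarray(cube.absorbance_nm, float)
    if wl[0] > cube.ex_nm[0] or wl[-1] < cube.em_nm[-1]:
        raise ValueError("absorbance grid must cover the excitation and emission ranges")

    corrected = np.empty_like(cube.data)
    flagged: list[str] = []
    for i in range(cube.n_samples):
        a = np.asarray(cube.absorbance[i], float)
        if np.any(~np.isfinite(a)):
            raise ValueError(f"missing absorbance for sample {cube.sample_ids[i]!r}")
        a_ex = np.interp(cube.ex_nm, wl, a)
        a_em = np.interp(cube.em_nm, wl, a)
        factor = 10.0 ** ((a_ex[:, None] + a_em[None, :]) / 2.0)
        corrected[i] = cube.data[i] * factor
        if a.max() > max_absorbance:
            flagged.append(cube.sample_ids[i])
    out = EEMCube(
        sample_ids=list(cube.sample_ids),
        ex_nm=cube.ex_nm,
        em_nm=cube.em_nm,
        data=corrected,
        absorbance_nm=cube.absorbance_nm,
        absorbance=cube.absorbance,
        doc_mg_l=cube.doc_mg_l,
    )
    return out, flagged


def excise_scatter(cube: EEMCube, width_nm: float = 10.0) -> EEMCube:
    """Mask (NaN) a band of ``+-width_nm`` around first-order Rayleigh scatter.

    The fit treats NaNs as missing data, so excised pixels carry no weight.
    Off by default in the pipeline; used when the generator simulates
    scatter ridges.
    """
    mask = np.abs(cube.em_nm[None, :] - cube.ex_nm[:, None]) <= width_nm
    data = cube.data.copy()
    data[:, mask] = np.nan
    return EEMCube(
        sample_ids=list(cube.sample_ids),
        ex_nm=cube.ex_nm,
        em_nm=cube.em_nm,
        data=data,
        absorbance_nm=cube.absorbance_nm,
        absorbance=cube.absorbance,
        doc_mg_l=cube.doc_mg_l,
    )


# ---------------------------------------------------------------------------
# PARAFAC model
# ---------------------------------------------------------------------------

def _khatri_rao(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    # row (j, k) -> b[j] * c[k]; column-wise Kronecker product
    return (b[:, None, :] * c[None, :, :]).reshape(b.shape[0] * c.shape[0], b.shape[1])


class ParafacModel:
    """Nonnegative trilinear (PARAFAC) decomposition of an EEM cube.

    Parameters
    ----------
    cube:
        The (corrected) EEM collection to decompose.
    n_components:
        Number of fluorophore components F; requires at least 2F samples.
    nonnegative:
        Constrain all three modes to be nonnegative (the physically
        meaningful choice for fluorescence; default True).

    ``fit`` runs alternating least squares from several random starts and
    keeps the solution with the highest explained variance.
    """

    def __init__(self, cube: EEMCube, n_components: int, nonnegative: bool = True):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if cube.n_samples < 2 * n_components:
            raise ValueError(
                f"need at least {2 * n_components} samples to fit {n_components} components"
            )
        self.cube = cube
        self.n_components = n_components
        self.nonnegative = nonnegative

    # -- internals ---------------------------------------------------------

    #: lower bound for nonnegative factor entries: keeps starved components
    #: alive so they can regrow (a column at exactly zero never recovers in
    #: column-wise ALS), while projection onto [eps, inf) stays the exact
    #: constrained minimizer, preserving the monotone objective
    _EPS = 1e-12

    @classmethod
    def _hals_update(cls, factor, gram, mttkrp, nonneg):
        """Exact column-wise least-squares update of one factor in place."""
        F = factor.shape[1]
        for f in range(F):
            denom = gram[f, f]
            if denom <= 1e-300:
                factor[:, f] = cls._EPS if nonneg else 0.0
                continue
            col = factor[:, f] + (mttkrp[:, f] - factor @ gram[:, f]) / denom
            if nonneg:
                np.maximum(col, cls._EPS, out=col)
            factor[:, f] = col
        return factor

    def _svd_init(self, Xw, rng):
        """Nonnegative SVD-flavoured start: positive parts of the leading
        singular vectors of the spectral unfoldings (the dominant-sign part),
        scores from one nonnegative least-squares pass.  Far less prone to
        the swamps random dense starts fall into when components overlap."""
        n, J, K = Xw.shape
        F = self.n_components

        def lead(unfold, dim):
            U, _, _ = np.linalg.svd(unfold, full_matrices=False)
            cols = []
            for f in range(min(F, U.shape[1])):
                u = U[:, f]
                pos, neg = np.maximum(u, 0), np.maximum(-u, 0)
                u = pos if np.linalg.norm(pos) >= np.linalg.norm(neg) else neg
                if u.max() <= 0:
                    u = rng.uniform(0.1, 1.0, size=dim)
                cols.append(u / max(u.max(), 1e-12))
            while len(cols) < F:
                cols.append(rng.uniform(0.1, 1.0, size=dim))
            return np.column_stack(cols)

        B = lead(Xw.transpose(1, 0, 2).reshape(J, n * K), J)
        C = lead(Xw.transpose(2, 0, 1).reshape(K, n * J), K)
        gram_diag = np.maximum(((B.T @ B) * (C.T @ C)).diagonal(), 1e-12)
        A = np.maximum(np.einsum("ijk,jf,kf->if", Xw, B, C), 1e-6) / gram_diag
        return A, B, C

    def _single_fit(self, X, mask, rng, tol, max_iter, init):
        n, J, K = X.shape
        F = self.n_components
        Xw = X.copy()
        if mask is not None:
            Xw[~mask] = 0.0  # start missing pixels at zero, impute below

        if isinstance(init, tuple):  # warm start from given factors
            A, B, C = (m.copy() for m in init)
        elif init == "svd":
            A, B, C = self._svd_init(Xw, rng)
        else:
            A = rng.uniform(0.1, 1.0, size=(n, F))
            B = rng.uniform(0.1, 1.0, size=(J, F))
            C = rng.uniform(0.1, 1.0, size=(K, F))

        xnorm2 = float(np.sum(Xw * Xw))
        history = []
        prev = np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            if mask is not None:
                model = np.einsum("if,jf,kf->ijk", A, B, C)
                Xw[~mask] = model[~mask]
                xnorm2 = float(np.sum(Xw * Xw))

            # mode 0 (scores)
            gram = (B.T @ B) * (C.T @ C)
            mttkrp = Xw.reshape(n, J * K) @ _khatri_rao(B, C)
            A = self._hals_update(A, gram, mttkrp, self.nonnegative)
            # mode 1 (excitation)
            gram = (A.T @ A) * (C.T @ C)
            mttkrp = Xw.transpose(1, 0, 2).reshape(J, n * K) @ _khatri_rao(A, C)
            B = self._hals_update(B, gram, mttkrp, self.nonnegative)
            # mode 2 (emission)
            gram = (A.T @ A) * (B.T @ B)
            mttkrp = Xw.transpose(2, 0, 1).reshape(K, n * J) @ _khatri_rao(A, B)
            C = self._hals_update(C, gram, mttkrp, self.nonnegative)

            # RSS is exact after the final mode-2 update
            rss = xnorm2 - 2.0 * float(np.sum(C * mttkrp)) + float(np.sum((C.T @ C) * gram))
            rss = max(rss, 0.0)
            history.append(rss)

            # rebalance scale into the scores for conditioning
            for M_ in (B, C):
                scale = M_.max(axis=0)
                scale[scale <= 0] = 1.0
                M_ /= scale
                A *= scale

            if prev < np.inf and abs(prev - rss) <= tol * max(prev, 1e-300):
                converged = True
                break
            prev = rss

        return A, B, C, np.asarray(history), converged, n_iter

    # -- public API --------------------------------------------------------

    def fit(
        self,
        n_starts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 2000,
        refine_max_iter: int = 20000,
        seed: int | None = None,
    ) -> "ParafacResults":
        """Fit by multi-start alternating least squares (deterministic per seed).

        Each start (one SVD-flavoured, the rest random) runs at most
        ``max_iter`` sweeps.  The best few starts by explained variance are
        then refined until the tolerance is met or ``refine_max_iter`` total
        sweeps have been spent, and the best refined solution wins.
        Overlapping fluorophores put ALS in long near-flat swamps where the
        variance ranking at the cap is unreliable, so more than one
        candidate deserves the longer leash.
        """
        X = self.cube.data
        mask = None
        if np.any(np.isnan(X)):
            mask = ~np.isnan(X)
        rng = np.random.default_rng(seed)

        def ev_of(A, B, C):
            resid = X - np.einsum("if,jf,kf->ijk", A, B, C)
            rss = float(np.nansum(resid * resid))
            return 1.0 - rss / denom if denom > 0 else 1.0

        candidates = []
        start_variances = []
        denom = float(np.nansum(X * X))
        for start in range(n_starts):
            A, B, C, history, converged, n_iter = self._single_fit(
                X, mask, rng, tol, max_iter, init="svd" if start == 0 else "random"
            )
            ev = ev_of(A, B, C)
            start_variances.append(ev)
            candidates.append((ev, start, A, B, C, history, converged, n_iter))

        candidates.sort(key=lambda c: (-c[0], c[1]))
        best = None
        for ev, _, A, B, C, history, converged, n_iter in candidates[:3]:
            if not converged and refine_max_iter > n_iter:
                A, B, C, more, converged, extra = self._single_fit(
                    X, mask, rng, tol, refine_max_iter - n_iter, init=(A, B, C)
                )
                history = np.concatenate([history, more])
                n_iter += extra
                ev = ev_of(A, B, C)
            if best is None or ev > best[0]:
                best = (ev, A, B, C, history, converged, n_iter)

        ev, A, B, C, history, converged, n_iter = best
        # unit-maximum loadings; magnitude lives in the scores
        for M_ in (B, C):
            scale = M_.max(axis=0)
            scale[scale <= 0] = 1.0
            M_ /= scale
            A *= scale
        # entries held at the optimizer's positivity floor are not detections
        A[A < 1e-9 * max(A.max(), 1e-300)] = 0.0
        # order components by total score for a stable presentation
        order = np.argsort(-A.sum(axis=0))
        return ParafacResults(
            model=self,
            scores=A[:, order],
            ex_loadings=B[:, order],
            em_loadings=C[:, order],
            explained_variance=ev,
            converged=converged,
            n_iter=n_iter,
            loss_history=history,
            start_explained_variances=np.asarray(start_variances),
        )


@dataclass
class ParafacResults:
    """Fitted PARAFAC factors plus diagnostics.

    Loadings are column-normalized to unit maximum; the sample scores carry
    the magnitude, so ``reconstruction()`` is invariant to that choice.
    A fit that exhausted ``max_iter`` without meeting the tolerance is
    returned with ``converged=False`` rather than truncated.
    """

    model: ParafacModel
    scores: np.ndarray
    ex_loadings: np.ndarray
    em_loadings: np.ndarray
    explained_variance: float
    converged: bool
    n_iter: int
    loss_history: np.ndarray
    start_explained_variances: np.ndarray
    split_half: "SplitHalfReport | None" = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruction(self) -> np.ndarray:
        return np.einsum(
            "if,jf,kf->ijk", self.scores, self.ex_loadings, self.em_loadings
        )

    def peak_wavelengths(self) -> pd.DataFrame:
        """Argmax excitation/emission wavelength of each component."""
        ex = self.model.cube.ex_nm[np.argmax(self.ex_loadings, axis=0)]
        em = self.model.cube.em_nm[np.argmax(self.em_loadings, axis=0)]
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "ex_peak_nm": ex,
                "em_peak_nm": em,
                "total_score": self.scores.sum(axis=0),
            }
        )

    def summary(self) -> str:
        peaks = self.peak_wavelengths()
        lines = [
            "Nonnegative PARAFAC decomposition",
            f"  samples: {self.model.cube.n_samples}   components: {self.n_components}",
            f"  explained variance: {self.explained_variance:.4%}",
            f"  converged: {self.converged} (iterations: {self.n_iter})",
            "",
            "  comp   ex peak (nm)   em peak (nm)   total score",
        ]
        for _, r in peaks.iterrows():
            lines.append(
                f"  C{int(r['component']):<5d}{r['ex_peak_nm']:>9.0f}{r['em_peak_nm']:>15.0f}"
                f"{r['total_score']:>15.3f}"
            )
        if self.split_half is not None:
            lines += [
                "",
                f"  split-half congruence (min over splits): "
                f"{np.min(self.split_half.congruence):.4f} "
                f"({'pass' if self.split_half.passed else 'FAIL'})",
            ]
        return "\n".join(lines)

    def plot_components(self, ax=None):
        """Spectral loadings per component (excitation dashed, emission solid)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ex_nm, em_nm = self.model.cube.ex_nm, self.model.cube.em_nm
        for f in range(self.n_components):
            (line,) = ax.plot(em_nm, self.em_loadings[:, f], label=f"C{f + 1}")
            ax.plot(ex_nm, self.ex_loadings[:, f], linestyle="--", color=line.get_color())
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("loading (unit max)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# validation and matching
# ---------------------------------------------------------------------------

def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Congruence coefficient (uncentred cosine) between two loading vectors."""
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def _greedy_bijection(congruence: np.ndarray):
    """Greedy one-to-one assignment, highest congruence first.

    Ties are broken by (row, column) index order via lexicographic argmax.
    """
    c = congruence.copy()
    n = min(c.shape)
    pairs = {}
    for _ in range(n):
        idx = np.unravel_index(np.nanargmax(c), c.shape)
        pairs[idx[0]] = idx[1]
        c[idx[0], :] = -np.inf
        c[:, idx[1]] = -np.inf
    return pairs


@dataclass
class SplitHalfReport:
    """Per-component Tucker congruence between independently fitted halves."""

    congruence: np.ndarray  # (n_splits, F) matched congruences
    threshold: float
    passed: bool
    split_assignments: list[dict[int, int]] = field(default_factory=list)


def split_half_validate(
    cube: EEMCube,
    n_components: int,
    n_splits: int = 2,
    congruence_threshold: float = 0.95,
    n_starts: int = 4,
    tol: float = 1e-8,
    max_iter: int = 2000,
    refine_max_iter: int = 20000,
    seed: int | None = None,
) -> SplitHalfReport:
    """Validate a component count by refitting on random sample halves.

    For each split the samples are randomly divided in two, each half is fit
    independently, and components are matched greedily by Tucker congruence
    of the concatenated excitation+emission loadings.  The report passes
    when every matched congruence, over all splits, reaches the threshold.
    """
    rng = np.random.default_rng(seed)
    n = cube.n_samples
    if n < 4 * n_components:
        raise ValueError("too few samples to fit both halves")
    rows = []
    assignments = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2 :])
        fits = []
        for half in halves:
            sub = cube.subset(np.sort(half))
            res = ParafacModel(sub, n_components).fit(
                n_starts=n_starts,
                tol=tol,
                max_iter=max_iter,
                refine_max_iter=refine_max_iter,
                seed=int(rng.integers(2**31 - 1)),
            )
            fits.append(res)
        la = np.vstack([fits[0].ex_loadings, fits[0].em_loadings])
        lb = np.vstack([fits[1].ex_loadings, fits[1].em_loadings])
        cmat = np.array(
            [
                [tucker_congruence(la[:, i], lb[:, j]) for j in range(n_components)]
                for i in range(n_components)
            ]
        )
        pairs = _greedy_bijection(cmat)
        rows.append([cmat[i, j] for i, j in sorted(pairs.items())])
        assignments.append(pairs)
    congruence = np.asarray(rows)
    return SplitHalfReport(
        congruence=congruence,
        threshold=congruence_threshold,
        passed=bool(np.min(congruence) >= congruence_threshold),
        split_assignments=assignments,
    )


@dataclass
class ComponentAssignment:
    """Bijective mapping from fitted components to reference labels."""

    labels: list[str]            # per fitted component
    congruence: np.ndarray       # per fitted component, against its match
    peaks: pd.DataFrame          # fitted argmax wavelengths per component

    def component_for(self, label: str) -> int:
        """Index of the fitted component carrying this reference label."""
        return self.labels.index(label)


def match_components(
    results: ParafacResults, reference: ReferenceSpectra = DEFAULT_REFERENCE
) -> ComponentAssignment:
    """Assign each fitted component the best-matching reference label.

    Matching maximizes Tucker congruence of concatenated excitation and
    emission loadings against Gaussian reference profiles, greedily with
    exclusion so the assignment is a bijection.
    """
    ex_ref, em_ref = reference.profiles(
        results.model.cube.ex_nm, results.model.cube.em_nm
    )
    fitted = np.vstack([results.ex_loadings, results.em_loadings])
    refmat = np.vstack([ex_ref, em_ref])
    F = results.n_components
    cmat = np.array(
        [
            [tucker_congruence(fitted[:, i], refmat[:, j]) for j in range(reference.n_components)]
            for i in range(F)
        ]
    )
    pairs = _greedy_bijection(cmat)
    labels = [reference.labels[pairs[i]] for i in range(F)] if F <= reference.n_components else None
    if labels is None:
        raise ValueError("more fitted components than reference spectra")
    return ComponentAssignment(
        labels=labels,
        congruence=np.array([cmat[i, pairs[i]] for i in range(F)]),
        peaks=results.peak_wavelengths(),
    )


# ---------------------------------------------------------------------------
# phenol index
# ---------------------------------------------------------------------------

def phenol_index(
    results: ParafacResults,
    cube: EEMCube,
    assignment: ComponentAssignment,
    phenol_label: str = "phenol-leachate",
) -> pd.DataFrame:
    """Relative phenol concentration per sample.

    The proportional fluorescence of the phenol-leachate component
    (score / sum of all component scores, defined as 0 when all scores are
    zero) is multiplied by porewater DOC (mg/L).
    """
    if cube.doc_mg_l is None:
        raise ValueError("cube carries no DOC concentrations")
    f = assignment.component_for(phenol_label)
    totals = results.scores.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(totals > 0, results.scores[:, f] / totals, 0.0)
    return pd.DataFrame(
        {
            "sample_id": cube.sample_ids,
            "proportion_phenol": proportion,
            "doc_mg_l": cube.doc_mg_l,
            "phenol_index": proportion * cube.doc_mg_l,
        }
    )
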