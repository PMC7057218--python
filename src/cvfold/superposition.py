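"""Superposition of small, possibly discontinuous folds onto structures.

Correspondences come from the fold search; the rigid transform minimising
the r.m.s.d. over the corresponding atoms is the weighted Kabsch solution,
refined by iteratively reweighting each atom pair with the inverse of its
residual variance so that outlying pairs stop steering the fit.  For
fragments longer than five residues up to three residues may be trimmed
from either extremity; every trim combination is evaluated and the lowest
r.m.s.d. core wins.  Non-overlapping sites are reported separately.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

from .annotation import AnnotatedStructure
from .fold_library import (FoldMatch, FoldMatrix, MatchConfig,
                           build_fold_matrix, find_fold_occurrences)

VARIANCE_EPS = 1e-4          # A^2, floors inverse-variance weights
TRIM_MIN_FRAGMENT = 5        # only fragments with more residues are trimmed
TRIM_MAX = 3
TRIM_ENUM_LIMIT = 100_000


class DegenerateSuperpositionError(ValueError):
    """Fewer than three pairs, or a collinear coordinate set."""


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                weights: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid superposition of A onto B.

    Returns (rotation, translation, rmsd) with ``R @ a + t ~ b`` and
    det(R) = +1 (proper rotation, mirror images are never matched).  The
    reported r.m.s.d. is unweighted, over all pairs.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise DegenerateSuperpositionError("need at least three atom pairs")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    ca = (w[:, None] * A).sum(axis=0)
    cb = (w[:, None] * B).sum(axis=0)
    A0 = A - ca
    B0 = B - cb
    H = (w[:, None] * A0).T @ B0
    if np.linalg.matrix_rank(H) < 2:
        raise DegenerateSuperpositionError("collinear or degenerate set")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return R, t, rmsd


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    core: list[tuple[tuple[int, int], tuple[int, int]]]  # residue key pairs
    rmsd: float
    trimmed: list[tuple[int, int]]
    site_index: int = 0
    weights: np.ndarray | None = None
    n_iterations: int = 0


def weighted_refine(coords_a: np.ndarray, coords_b: np.ndarray,
                    max_iterations: int = 20, tol: float = 1e-6
                    ) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, int]:
    """Iterative inverse-variance superposition of A onto B.

    Each round superposes with the current weights, measures per-pair
    squared residuals and resets the weights to 1 / (residual^2 + eps),
    normalised to mean 1; stops when the r.m.s.d. changes by less than
    ``tol`` or after ``max_iterations``.

    Returns (rotation, translation, rmsd, weights, n_iterations), where
    the r.m.s.d. is the *weighted* one, sqrt(sum w d^2 / sum w): the
    quality of the fit over the consistent core, insensitive to the pairs
    the iteration has downweighted.  Since the weights decrease with the
    residuals, it never exceeds the plain unweighted r.m.s.d.
    """

    def wrmsd(R, t, w):
        diff = (coords_a @ R.T + t) - coords_b
        return float(np.sqrt(np.sum(w * np.sum(diff ** 2, axis=1)) / w.sum()))

    n = len(coords_a)
    w = np.ones(n)
    R, t, _ = kabsch_rmsd(coords_a, coords_b, w)
    rmsd = wrmsd(R, t, w)
    for it in range(1, max_iterations + 1):
        diff = (coords_a @ R.T + t) - coords_b
        var = np.sum(diff ** 2, axis=1)
        w = 1.0 / (var + VARIANCE_EPS)
        w = w / w.mean()
        R, t, _ = kabsch_rmsd(coords_a, coords_b, w)
        new_rmsd = wrmsd(R, t, w)
        if abs(new_rmsd - rmsd) < tol:
            return R, t, new_rmsd, w, it
        rmsd = new_rmsd
    return R, t, rmsd, w, max_iterations


def match_pairing(match: FoldMatch, template_ann: AnnotatedStructure,
                  target_ann: AnnotatedStructure,
                  atoms: Sequence[str] = ("CA",)
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Paired coordinate arrays (template, target) over a match's core."""
    tpl, tgt = [], []
    for tpl_res, tgt_res in match.correspondence:
        for (tsi, tri), (gsi, gri) in zip(tpl_res, tgt_res):
            a = template_ann.stretches[tsi].residues[tri]
            b = target_ann.stretches[gsi].residues[gri]
            for name in atoms:
                tpl.append(a.coord(name))
                tgt.append(b.coord(name))
    return np.array(tpl), np.array(tgt)


def _trim_options(n_residues: int) -> list[tuple[int, int]]:
    """Trim combinations (n_cut, c_cut) for one fragment."""
    if n_residues <= TRIM_MIN_FRAGMENT:
        return [(0, 0)]
    room = n_residues - 3          # keep at least a tripeptide
    cmax = min(TRIM_MAX, room)
    return [(a, b) for a in range(cmax + 1) for b in range(cmax + 1)
            if n_residues - a - b >= 3]


@dataclasses.dataclass
class SuperposeConfig:
    match: MatchConfig = dataclasses.field(default_factory=MatchConfig)
    atoms: tuple[str, ...] = ("N", "CA", "C", "O")
    refine: bool = True


def _trimmed_pairing(match: FoldMatch, trims: Sequence[tuple[int, int]]
                     ) -> list[tuple[list, list]]:
    out = []
    for (tpl_res, tgt_res), (a, b) in zip(match.correspondence, trims):
        stop = len(tpl_res) - b
        out.append((tpl_res[a:stop], tgt_res[a:stop]))
    return out


def superpose_match(match: FoldMatch, template_ann: AnnotatedStructure,
                    target_ann: AnnotatedStructure,
                    config: SuperposeConfig | None = None
                    ) -> SuperpositionResult:
    """Best trim combination and refined transform for one match site.

    Enumerates every allowed (n_cut, c_cut) per eligible fragment (full
    Cartesian product, greedy per-fragment fallback above
    ``TRIM_ENUM_LIMIT`` combinations) and keeps the lowest r.m.s.d.
    """
    config = config or SuperposeConfig()
    frag_sizes = [len(tpl) for tpl, _ in match.correspondence]
    options = [_trim_options(n) for n in frag_sizes]
    n_combo = int(np.prod([len(o) for o in options]))

    def evaluate(trims):
        trimmed = _trimmed_pairing(match, trims)
        sub = dataclasses.replace(match, correspondence=trimmed)
        tpl_xyz, tgt_xyz = match_pairing(sub, template_ann, target_ann,
                                         atoms=config.atoms)
        if config.refine:
            R, t, rmsd, w, it = weighted_refine(tpl_xyz, tgt_xyz)
        else:
            R, t, rmsd = kabsch_rmsd(tpl_xyz, tgt_xyz)
            w, it = None, 0
        return rmsd, (R, t, w, it, trimmed)

    # strict improvement beyond noise, so ties keep the least-trimmed core
    best = None
    if n_combo <= TRIM_ENUM_LIMIT:
        for trims in itertools.product(*options):
            rmsd, payload = evaluate(trims)
            if best is None or rmsd < best[0] - 1e-12:
                best = (rmsd, trims, payload)
    else:
        # greedy: optimise one fragment's trim at a time
        trims = [(0, 0)] * len(options)
        rmsd, payload = evaluate(trims)
        best = (rmsd, tuple(trims), payload)
        for k, opts in enumerate(options):
            for opt in opts:
                cand = list(best[1])
                cand[k] = opt
                rmsd, payload = evaluate(tuple(cand))
                if rmsd < best[0] - 1e-12:
                    best = (rmsd, tuple(cand), payload)
    rmsd, trims, (R, t, w, it, trimmed) = best
    core = [(a, b) for tpl_res, tgt_res in trimmed
            for a, b in zip(tpl_res, tgt_res)]
    return SuperpositionResult(rotation=R, translation=t, core=core,
                               rmsd=rmsd, trimmed=list(trims), weights=w,
                               n_iterations=it)


def superpose_fold(template_ann: AnnotatedStructure,
                   target_ann: AnnotatedStructure,
                   config: SuperposeConfig | None = None
                   ) -> list[SuperpositionResult]:
    """Locate and superpose a small fold at every non-overlapping site.

    Runs the fold search, refines each match with the trim/weight scheme
    and suppresses any site sharing a target residue with a better
    (lower r.m.s.d., ties to the earlier residue range) site.  An empty
    list means the fold was not found; it is not an error.
    """
    config = config or SuperposeConfig()
    template = build_fold_matrix(template_ann)
    target = build_fold_matrix(target_ann)
    matches = find_fold_occurrences(template, target, config.match)
    results = []
    for match in matches:
        res = superpose_match(match, template_ann, target_ann, config)
        res_keys = frozenset(k for _, k in res.core)
        results.append((res, res_keys))
    results.sort(key=lambda rk: (rk[0].rmsd, sorted(rk[1])))
    kept: list[SuperpositionResult] = []
    used: list[frozenset] = []
    for res, keys in results:
        if any(keys & u for u in used):
            continue
        res.site_index = len(kept)
        kept.append(res)
        used.append(keys)
    return kept
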