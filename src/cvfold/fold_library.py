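"""Fold representation, recursive fold search and library generation.

A fold is represented by a square matrix over the structure's CVs: the
main diagonal stores each CV's modulus and secondary-structure label, the
second diagonal the (angle, distance) relation between consecutive CVs --
enough to recognise secondary-structure elements in linear time -- and the
off-diagonal cells the (angle, distance) relations across fragments, which
encode the fold itself.  Searching a template fold in a target structure
is a depth-first traversal over candidate fragment assignments: intra-
fragment relations gate each candidate (secondary-structure similarity),
and inter-fragment relations against everything already assigned prune
the branch (tertiary similarity).  Pruning uses an optimistic bound, so
every assignment satisfying both thresholds is found.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import (AnnotatedStructure, Fragment, ScoringParams,
                         annotate_structure)
from .structures import ConnectedStretch, parse_structure, write_structure

MODEL_NAME_RE = re.compile(r"^(?P<pdbid>[A-Za-z0-9]+)_(?P<x>\d+)_(?P<yyyy>\d{1,4})\.pdb$")


class UnusableTemplateError(ValueError):
    """Template annotates to no helix or strand fragment."""


@dataclasses.dataclass
class MatchConfig:
    ss_threshold: float = 45.0       # %, intra-fragment similarity
    tt_threshold: float = 55.0       # %, inter-fragment similarity
    angle_tolerance: float = 15.0    # deg, full-credit band
    distance_tolerance: float = 2.0  # A, full-credit band
    coil_tolerance_factor: float = 2.0
    require_connectivity: bool = False
    multi_chain: bool = False


@dataclasses.dataclass
class FoldMatrix:
    """Annotated CV matrix of one structure (or of a template fold)."""

    annotated: AnnotatedStructure

    @property
    def order(self) -> int:
        return len(self.annotated.graph)

    @property
    def diag(self) -> list[tuple[float, str]]:
        labels = self.cv_labels()
        return [(cv.modulus, labels[i])
                for i, cv in enumerate(self.annotated.graph.cvs)]

    @property
    def second_diag(self) -> list[tuple[float, float]]:
        g = self.annotated.graph
        out = []
        for i in range(self.order - 1):
            out.append((float(g.angles[i, i + 1]), float(g.distances[i, i + 1])))
        return out

    def cv_labels(self) -> list[str]:
        """Per-CV label: the fragment's label for member CVs, else coil."""
        labels = ["coil"] * self.order
        for frag in self.annotated.fragments:
            for ci in frag.cv_indices:
                labels[ci] = frag.label
        return labels

    @property
    def fragment_index(self) -> dict[int, int]:
        return {ci: fi for fi, frag in enumerate(self.annotated.fragments)
                for ci in frag.cv_indices}

    @property
    def fragments(self) -> list[Fragment]:
        return self.annotated.fragments

    def cell(self, i: int, j: int) -> tuple[float, float]:
        g = self.annotated.graph
        return float(g.angles[i, j]), float(g.distances[i, j])


def build_fold_matrix(annotated: AnnotatedStructure) -> FoldMatrix:
    return FoldMatrix(annotated)


def _block_cells(cv_a: Sequence[int], cv_b: Sequence[int] | None = None
                 ) -> list[tuple[int, int]]:
    if cv_b is None:
        return [(cv_a[i], cv_a[j]) for i in range(len(cv_a))
                for j in range(i + 1, len(cv_a))]
    return [(i, j) for i in cv_a for j in cv_b]


def score_similarity(template: FoldMatrix, template_cells: Sequence[tuple[int, int]],
                     target: FoldMatrix, target_cells: Sequence[tuple[int, int]],
                     config: MatchConfig | None = None) -> float:
    """Percentage of corresponding (angle, distance) cells within tolerance.

    A cell matches when both the angle and the distance differences fall
    inside their bands; cells involving a coil CV in the template use
    doubled tolerances.  Empty comparisons score 100.
    """
    config = config or MatchConfig()
    if len(template_cells) != len(target_cells):
        raise ValueError("cell lists must correspond one-to-one")
    if not template_cells:
        return 100.0
    labels = template.cv_labels()
    n_ok = 0
    for (ti, tj), (si, sj) in zip(template_cells, target_cells):
        a1, d1 = template.cell(ti, tj)
        a2, d2 = target.cell(si, sj)
        factor = (config.coil_tolerance_factor
                  if labels[ti] == "coil" or labels[tj] == "coil" else 1.0)
        ang_ok = (np.isfinite(a1) and np.isfinite(a2)
                  and abs(a1 - a2) <= config.angle_tolerance * factor)
        dist_ok = abs(d1 - d2) <= config.distance_tolerance * factor
        if ang_ok and dist_ok:
            n_ok += 1
    return 100.0 * n_ok / len(template_cells)


@dataclasses.dataclass
class FoldMatch:
    """One occurrence of the template fold in a target structure."""

    source: str
    model_index: int
    assignment: list[tuple[int, int]]      # (target fragment idx, CV offset)
    correspondence: list[tuple[list[tuple[int, int]], list[tuple[int, int]]]]
    ss_score: float
    tt_score: float
    connectivity_ok: bool
    rmsd_to_template: float | None = None

    def target_residue_keys(self) -> list[tuple[int, int]]:
        out = []
        for _, tgt in self.correspondence:
            out.extend(tgt)
        return out

    def template_residue_keys(self) -> list[tuple[int, int]]:
        out = []
        for tpl, _ in self.correspondence:
            out.extend(tpl)
        return out


def _candidate_windows(tpl_frag: Fragment, tgt_frag: Fragment,
                       template: FoldMatrix, target: FoldMatrix,
                       config: MatchConfig) -> tuple[int, float] | None:
    """Best CV-window offset of the template fragment inside a target
    fragment, or None if the fragment is unusable (wrong type / too short).

    The offset is chosen by intra-fragment similarity alone (ties to the
    smallest offset), independent of any threshold, so raising thresholds
    can only shrink the candidate set.
    """
    if tpl_frag.label != tgt_frag.label:
        return None
    m = len(tpl_frag.cv_indices)
    n = len(tgt_frag.cv_indices)
    if n < m or m == 0:
        return None
    tpl_cells = _block_cells(tpl_frag.cv_indices)
    best_off, best_score = 0, -1.0
    for off in range(n - m + 1):
        window = tgt_frag.cv_indices[off:off + m]
        score = score_similarity(template, tpl_cells, target,
                                 _block_cells(window), config)
        if score > best_score:
            best_off, best_score = off, score
    return best_off, best_score


def _window_residues(frag: Fragment, offset: int, n_cvs: int,
                     window: int = 3) -> list[tuple[int, int]]:
    start = frag.start + offset
    return [(frag.stretch_index, start + k)
            for k in range(n_cvs + window - 1)]


def find_fold_occurrences(template: FoldMatrix, target: FoldMatrix,
                          config: MatchConfig | None = None,
                          source: str = "target", model_index: int = 0
                          ) -> list[FoldMatch]:
    """All assignments of target fragments to the template's fragments that
    satisfy the intra (ss) and inter (tt) thresholds.

    Complete by construction: candidates are only discarded when their
    intra score fails, and branches only when even perfect scores on the
    remaining fragment pairs could not lift the aggregate inter score to
    the threshold.
    """
    config = config or MatchConfig()
    tpl_frags = template.fragments
    if not tpl_frags:
        raise UnusableTemplateError("template has no helix or strand fragment")
    tgt_frags = target.fragments
    K = len(tpl_frags)

    # candidate lists per template fragment: (target frag idx, offset, score)
    candidates: list[list[tuple[int, int, float]]] = []
    for tf in tpl_frags:
        row = []
        for gi, gf in enumerate(tgt_frags):
            got = _candidate_windows(tf, gf, template, target, config)
            if got is None:
                continue
            off, score = got
            if score >= config.ss_threshold:
                row.append((gi, off, score))
        candidates.append(row)

    # inter-fragment cell counts per template pair, for the optimistic bound
    pair_cells = {}
    for a in range(K):
        for b in range(a + 1, K):
            pair_cells[(a, b)] = len(tpl_frags[a].cv_indices) * len(tpl_frags[b].cv_indices)
    total_cells = sum(pair_cells.values())

    # a template whose fragments already span several chains (a coiled
    # coil, a fixture with one chain per element) must be allowed to match
    # cross-chain sites even in single-chain mode
    tpl_chains = {template.annotated.stretches[f.stretch_index].residues[0].chain_id
                  for f in tpl_frags}
    single_chain = not config.multi_chain and len(tpl_chains) <= 1
    matches: list[FoldMatch] = []

    def chain_of(frag: Fragment) -> str:
        stretch = target.annotated.stretches[frag.stretch_index]
        return stretch.residues[0].chain_id

    def dfs(level: int, assigned: list[tuple[int, int, float]],
            ok_cells: float, done_cells: int) -> None:
        if level == K:
            tt = (100.0 * ok_cells / total_cells) if total_cells else 100.0
            if tt + 1e-9 < config.tt_threshold:
                return
            matches.append(_finalize(assigned, tt))
            return
        for gi, off, score in candidates[level]:
            if any(gi == g for g, _, _ in assigned):
                continue
            if single_chain and assigned:
                if chain_of(tgt_frags[gi]) != chain_of(tgt_frags[assigned[0][0]]):
                    continue
            new_ok = ok_cells
            new_done = done_cells
            feasible = True
            for prev_level, (g_prev, off_prev, _) in enumerate(assigned):
                a, b = sorted((prev_level, level))
                frag_a, off_a = ((g_prev, off_prev) if a == prev_level
                                 else (gi, off))
                frag_b, off_b = ((gi, off) if b == level else (g_prev, off_prev))
                ta, tb = tpl_frags[a], tpl_frags[b]
                wa = tgt_frags[frag_a].cv_indices[off_a:off_a + len(ta.cv_indices)]
                wb = tgt_frags[frag_b].cv_indices[off_b:off_b + len(tb.cv_indices)]
                tpl_cells = _block_cells(ta.cv_indices, tb.cv_indices)
                pct = score_similarity(template, tpl_cells, target,
                                       _block_cells(wa, wb), config)
                ncells = pair_cells[(a, b)]
                new_ok += pct / 100.0 * ncells
                new_done += ncells
            if total_cells:
                bound = 100.0 * (new_ok + (total_cells - new_done)) / total_cells
                feasible = bound + 1e-9 >= config.tt_threshold
            if feasible:
                dfs(level + 1, assigned + [(gi, off, score)], new_ok, new_done)

    def _finalize(assigned: list[tuple[int, int, float]], tt: float) -> FoldMatch:
        correspondence = []
        order_keys = []
        for k, (gi, off, _) in enumerate(assigned):
            tf, gf = tpl_frags[k], tgt_frags[gi]
            tpl_res = [(tf.stretch_index, r) for r in range(tf.start, tf.stop + 1)]
            tgt_res = _window_residues(gf, off, len(tf.cv_indices))
            correspondence.append((tpl_res, tgt_res))
            order_keys.append((gf.stretch_index, gf.start + off))
        conn_ok = order_keys == sorted(order_keys)
        ss = float(np.mean([s for _, _, s in assigned]))
        return FoldMatch(source=source, model_index=model_index,
                         assignment=[(g, o) for g, o, _ in assigned],
                         correspondence=correspondence, ss_score=ss,
                         tt_score=tt, connectivity_ok=conn_ok)

    dfs(0, [], 0.0, 0)
    # residue-level overlap between different fragments of one match is
    # impossible (fragments are disjoint), but drop duplicate assignments
    if config.require_connectivity:
        matches = [m for m in matches if m.connectivity_ok]
    matches.sort(key=lambda m: (-m.tt_score, -m.ss_score, m.assignment))
    return matches


def brute_force_fold_occurrences(template: FoldMatrix, target: FoldMatrix,
                                 config: MatchConfig | None = None,
                                 source: str = "target", model_index: int = 0
                                 ) -> list[FoldMatch]:
    """Exhaustive enumeration over all ordered fragment tuples (oracle).

    Uses the same per-fragment window choice as the recursive search but
    no pruning: every tuple is fully scored and tested against both
    thresholds.  Intended for small targets.
    """
    import itertools
    config = config or MatchConfig()
    tpl_frags = template.fragments
    if not tpl_frags:
        raise UnusableTemplateError("template has no helix or strand fragment")
    tgt_frags = target.fragments
    K = len(tpl_frags)
    tpl_chains = {template.annotated.stretches[f.stretch_index].residues[0].chain_id
                  for f in tpl_frags}
    single_chain = not config.multi_chain and len(tpl_chains) <= 1
    matches = []
    for combo in itertools.permutations(range(len(tgt_frags)), K):
        assigned = []
        ok = True
        for k, gi in enumerate(combo):
            got = _candidate_windows(tpl_frags[k], tgt_frags[gi], template,
                                     target, config)
            if got is None or got[1] < config.ss_threshold:
                ok = False
                break
            assigned.append((gi, got[0], got[1]))
        if not ok:
            continue
        if single_chain:
            chains = {target.annotated.stretches[tgt_frags[g].stretch_index]
                      .residues[0].chain_id for g, _, _ in assigned}
            if len(chains) > 1:
                continue
        ok_cells = 0.0
        total = 0
        for a in range(K):
            for b in range(a + 1, K):
                ta, tb = tpl_frags[a], tpl_frags[b]
                ga, oa, _ = assigned[a]
                gb, ob, _ = assigned[b]
                wa = tgt_frags[ga].cv_indices[oa:oa + len(ta.cv_indices)]
                wb = tgt_frags[gb].cv_indices[ob:ob + len(tb.cv_indices)]
                pct = score_similarity(template,
                                       _block_cells(ta.cv_indices, tb.cv_indices),
                                       target, _block_cells(wa, wb), config)
                n = len(ta.cv_indices) * len(tb.cv_indices)
                ok_cells += pct / 100.0 * n
                total += n
        tt = (100.0 * ok_cells / total) if total else 100.0
        if tt + 1e-9 < config.tt_threshold:
            continue
        correspondence = []
        order_keys = []
        for k, (gi, off, _) in enumerate(assigned):
            tf, gf = tpl_frags[k], tgt_frags[gi]
            tpl_res = [(tf.stretch_index, r) for r in range(tf.start, tf.stop + 1)]
            correspondence.append((tpl_res, _window_residues(gf, off,
                                                             len(tf.cv_indices))))
            order_keys.append((gf.stretch_index, gf.start + off))
        conn_ok = order_keys == sorted(order_keys)
        if config.require_connectivity and not conn_ok:
            continue
        matches.append(FoldMatch(source=source, model_index=model_index,
                                 assignment=[(g, o) for g, o, _ in assigned],
                                 correspondence=correspondence,
                                 ss_score=float(np.mean([s for _, _, s in assigned])),
                                 tt_score=tt, connectivity_ok=conn_ok))
    matches.sort(key=lambda m: (-m.tt_score, -m.ss_score, m.assignment))
    return matches


def _matched_residues(match: FoldMatch, annotated: AnnotatedStructure
                      ) -> list:
    out = []
    for si, ri in match.target_residue_keys():
        out.append(annotated.stretches[si].residues[ri])
    return out


def apply_filters(matches: Iterable[FoldMatch], target: FoldMatrix,
                  sequence_pattern: str | None = None,
                  disulfide: bool = False,
                  disulfide_range: tuple[float, float] = (1.8, 2.5),
                  max_rmsd: float | None = None,
                  template: FoldMatrix | None = None) -> list[FoldMatch]:
    """Sequence-pattern, disulfide and r.m.s.d. filters.

    The pattern is matched position-wise against the one-letter sequence of
    the matched residues in template-fragment order; ``X`` is a wildcard.
    The disulfide filter demands at least one S-gamma pair inside the bond
    window.  ``max_rmsd`` superposes each match on the template (CA atoms)
    and drops it above the cut.
    """
    from .superposition import match_pairing, kabsch_rmsd

    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}
    out = []
    for match in matches:
        residues = _matched_residues(match, target.annotated)
        if sequence_pattern is not None:
            if len(sequence_pattern) != len(residues):
                continue
            seq = "".join(three_to_one.get(r.res_name, "X") for r in residues)
            if any(p != "X" and p != s
                   for p, s in zip(sequence_pattern.upper(), seq)):
                continue
        if disulfide:
            sgs = [r.coord("SG") for r in residues if "SG" in r.atoms]
            found = False
            for i in range(len(sgs)):
                for j in range(i + 1, len(sgs)):
                    d = float(np.linalg.norm(sgs[i] - sgs[j]))
                    if disulfide_range[0] <= d <= disulfide_range[1]:
                        found = True
            if not found:
                continue
        if max_rmsd is not None:
            if template is None:
                raise ValueError("max_rmsd filter needs the template matrix")
            tpl_xyz, tgt_xyz = match_pairing(match, template.annotated,
                                             target.annotated, atoms=("CA",))
            _, _, rmsd = kabsch_rmsd(tgt_xyz, tpl_xyz)
            match = dataclasses.replace(match, rmsd_to_template=rmsd)
            if rmsd > max_rmsd:
                continue
        out.append(match)
    return out


@dataclasses.dataclass
class LibraryModel:
    filename: str
    source: str
    model_index: int
    match: FoldMatch
    rmsd_to_template: float
    path: Path | None = None

    def __post_init__(self) -> None:
        if not MODEL_NAME_RE.match(self.filename):
            raise ValueError(f"bad library model name {self.filename!r}")


@dataclasses.dataclass
class LibraryConfig:
    match: MatchConfig = dataclasses.field(default_factory=MatchConfig)
    scoring: ScoringParams = dataclasses.field(default_factory=ScoringParams)
    max_rmsd: float = 5.0            # A, to the template
    common_b_factor: float = 25.0    # A^2
    sequence_pattern: str | None = None
    disulfide: bool = False
    id_list: Sequence[str] | None = None   # restrict database to these stems
    representative_chain_only: bool = True


def annotate_file(path: str | Path, scoring: ScoringParams | None = None,
                  model_index: int = 0,
                  representative_chain_only: bool = False) -> AnnotatedStructure:
    """Parse and annotate a PDB file.

    With ``representative_chain_only`` chains that duplicate an earlier
    chain's residue sequence (equivalent monomers of an assembly) are
    dropped, keeping the first occurrence.
    """
    stretches = parse_structure(path, model_index=model_index)
    if representative_chain_only:
        seen: dict[str, str] = {}
        keep_chains: set[str] = set()
        by_chain: dict[str, list] = {}
        for s in stretches:
            by_chain.setdefault(s.provenance.chain_id, []).append(s)
        for cid, chain_stretches in by_chain.items():
            signature = "|".join(r.res_name for s in chain_stretches for r in s)
            if signature not in seen:
                seen[signature] = cid
                keep_chains.add(cid)
        stretches = [s for s in stretches
                     if s.provenance.chain_id in keep_chains]
    return annotate_structure(stretches, scoring)


def superpose_match_on_template(match: FoldMatch, template: FoldMatrix,
                                target: FoldMatrix) -> tuple[list[ConnectedStretch], float]:
    """Extract the matched residues and superpose them onto the template."""
    from .superposition import match_pairing, kabsch_rmsd
    from .structures import transform_stretch

    tpl_xyz, tgt_xyz = match_pairing(match, template.annotated,
                                     target.annotated, atoms=("CA",))
    R, t, rmsd = kabsch_rmsd(tgt_xyz, tpl_xyz)
    pieces = []
    for _, tgt_res in match.correspondence:
        residues = [target.annotated.stretches[si].residues[ri]
                    for si, ri in tgt_res]
        piece = ConnectedStretch(residues,
                                 target.annotated.stretches[tgt_res[0][0]].provenance)
        pieces.append(transform_stretch(piece, R, t))
    return pieces, rmsd


def generate_library(template_pdb: str | Path, database: str | Path,
                     out_dir: str | Path,
                     config: LibraryConfig | None = None) -> list[LibraryModel]:
    """Run the five-step pipeline: annotate the template, annotate every
    database entry, extract all fold occurrences, filter, superpose on the
    template and write the models under ``out_dir`` with a common B factor
    and the pdbid_x_yyyy.pdb naming scheme."""
    config = config or LibraryConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tpl_ann = annotate_file(template_pdb, config.scoring)
    template = build_fold_matrix(tpl_ann)
    if not template.fragments:
        raise UnusableTemplateError(
            f"{template_pdb} annotates to no secondary-structure fragment")
    database = Path(database)
    files = sorted(database.glob("*.pdb")) if database.is_dir() else [database]
    if config.id_list is not None:
        keep = {s.lower() for s in config.id_list}
        files = [f for f in files if f.stem.lower() in keep]
    tpl_multi_chain = len({
        tpl_ann.stretches[f.stretch_index].residues[0].chain_id
        for f in template.fragments}) > 1
    models: list[LibraryModel] = []
    for f in files:
        pdbid = f.stem
        try:
            ann = annotate_file(
                f, config.scoring,
                representative_chain_only=(config.representative_chain_only
                                           and not config.match.multi_chain
                                           and not tpl_multi_chain))
        except Exception:
            continue
        target = build_fold_matrix(ann)
        matches = find_fold_occurrences(template, target, config.match,
                                        source=pdbid)
        matches = apply_filters(matches, target,
                                sequence_pattern=config.sequence_pattern,
                                disulfide=config.disulfide,
                                max_rmsd=config.max_rmsd, template=template)
        for match in matches:
            pieces, rmsd = superpose_match_on_template(match, template, target)
            counter = len(models) + 1
            name = f"{pdbid}_{match.model_index}_{counter:04d}.pdb"
            path = out_dir / name
            write_structure(pieces, path,
                            b_factor_override=config.common_b_factor)
            models.append(LibraryModel(filename=name, source=pdbid,
                                       model_index=match.model_index,
                                       match=match, rmsd_to_template=rmsd,
                                       path=path))
    return models


def cluster_library(models: Sequence[LibraryModel], mode: str = "pairwise_rmsd",
                    out_dir: str | Path | None = None,
                    rmsd_cut: float = 1.0,
                    rmsd_bins: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
                    n_random: int = 100, seed: int = 42
                    ) -> dict[int, list[LibraryModel]]:
    """Cluster library models.

    ``pairwise_rmsd``: complete-linkage on the exhaustive pairwise CA
    r.m.s.d. matrix, cut at ``rmsd_cut`` (deterministic).
    ``rmsd_range``: bin by r.m.s.d. to the template at ``rmsd_bins`` edges.
    ``random_subset``: a seeded sample of ``n_random`` models, one cluster.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    from .superposition import kabsch_rmsd

    models = list(models)
    clusters: dict[int, list[LibraryModel]] = {}
    if mode == "pairwise_rmsd":
        if len(models) == 1:
            clusters = {0: models}
        else:
            coords = [_model_ca(m) for m in models]
            n = len(models)
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    _, _, rmsd = kabsch_rmsd(coords[i], coords[j])
                    dm[i, j] = dm[j, i] = rmsd
            Z = linkage(squareform(dm, checks=False), method="complete")
            labels = fcluster(Z, t=rmsd_cut, criterion="distance")
            for lab, m in zip(labels, models):
                clusters.setdefault(int(lab) - 1, []).append(m)
    elif mode == "rmsd_range":
        edges = list(rmsd_bins)
        for m in models:
            b = int(np.searchsorted(edges, m.rmsd_to_template, side="right"))
            clusters.setdefault(b, []).append(m)
    elif mode == "random_subset":
        rng = np.random.default_rng(seed)
        k = min(n_random, len(models))
        idx = sorted(rng.choice(len(models), size=k, replace=False))
        clusters = {0: [models[i] for i in idx]}
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import shutil
        for cid, members in clusters.items():
            cdir = out_dir / f"cluster_{cid}"
            cdir.mkdir(exist_ok=True)
            for m in members:
                if m.path is not None:
                    shutil.copy(m.path, cdir / m.filename)
    return clusters


def _model_ca(model: LibraryModel) -> np.ndarray:
    stretches = parse_structure(model.path)
    return np.concatenate([s.ca_coords() for s in stretches])
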