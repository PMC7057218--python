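"""Secondary-structure annotation of CVs and residues.

Each CV is scored against an ideal helix and an ideal strand with a
penalty (pseudo-distance) function over three geometrical descriptors:

* CV modulus (ideal 2.2 A helix / 1.4 A strand),
* mean angle to the sequence-neighbouring CVs (ideal 7.5 deg / 52.5 deg),
* mean consecutive C-alpha spacing inside the window (ideal 3.80 A).

Each term is |observed - ideal| / scale clipped at 1 and the terms are
combined with fixed weights, so both scores live in [0, 1].  A CV is
labelled by the lower score only when the two scores differ by more than
the *strictness* threshold; otherwise it is coil.  Raising strictness
therefore annotates shorter, more ideal fragments.  A few context
iterations let neighbouring labels reinforce or weaken each hypothesis
before the labels are frozen and translated to residues.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (CVGraph, CharacteristicVector, build_cv_graph,
                       structure_cvs)
from .structures import ConnectedStretch, write_structure

AH, BS, COIL = "ah", "bs", "coil"


@dataclasses.dataclass
class ScoringParams:
    """Constants of the penalty function and of fragment/sheet grouping."""

    ideal_modulus: dict = dataclasses.field(
        default_factory=lambda: {AH: 2.2, BS: 1.4})
    ideal_angle: dict = dataclasses.field(
        default_factory=lambda: {AH: 7.5, BS: 52.5})
    ideal_ca_spacing: float = 3.80
    modulus_scale: float = 0.8          # A
    angle_scale: float = 45.0           # deg
    ca_spacing_scale: float = 0.5       # A
    weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    strictness_ah: float = 0.5
    strictness_bs: float = 0.3
    context_factor: float = 0.10        # +/- fraction per refinement pass
    max_iterations: int = 10
    min_fragment_len: int = 3
    # beta-sheet packing rule
    sheet_parallel_band: tuple[float, float] = (0.0, 30.0)
    sheet_antiparallel_band: tuple[float, float] = (150.0, 180.0)
    sheet_angle_fraction: float = 0.40
    sheet_max_distance: float = 6.0     # A, on the minimum CV-CV distance
    sheet_distance_stat: str = "min"    # or "mean"
    same_type_factor: float = 2.0       # fragment-graph weight bonus


@dataclasses.dataclass
class CVScore:
    score_ah: float
    score_bs: float
    label: str
    max_strictness: float

    @property
    def scores(self) -> dict:
        return {AH: self.score_ah, BS: self.score_bs}


def _descriptors(cv_index: int, graph: CVGraph,
                 stretches: Sequence[ConnectedStretch]) -> tuple[float, float | None, float]:
    """(modulus, mean neighbour angle or None, mean CA-CA spacing) of a CV."""
    cv = graph.cvs[cv_index]
    modulus = cv.modulus
    nb = graph.sequence_neighbours(cv_index)
    angs = [graph.angles[cv_index, j] for j in nb
            if np.isfinite(graph.angles[cv_index, j])]
    mean_angle = float(np.mean(angs)) if angs else None
    stretch = stretches[cv.stretch_index]
    ca = np.array([stretch.residues[i].ca for i in cv.window])
    spacing = float(np.mean(np.linalg.norm(np.diff(ca, axis=0), axis=1)))
    return modulus, mean_angle, spacing


def score_cv(cv_index: int, graph: CVGraph,
             stretches: Sequence[ConnectedStretch],
             params: ScoringParams | None = None) -> CVScore:
    """Penalty scores of one CV against the helix and strand hypotheses.

    Degenerate (zero-modulus) CVs score 1 on both hypotheses.  An isolated
    CV (no sequence neighbour) is scored on modulus and spacing only, with
    the weights renormalised.
    """
    params = params or ScoringParams()
    cv = graph.cvs[cv_index]
    if cv.degenerate:
        return CVScore(1.0, 1.0, COIL, 0.0)
    modulus, mean_angle, spacing = _descriptors(cv_index, graph, stretches)
    scores = {}
    for hyp in (AH, BS):
        terms = [min(1.0, abs(modulus - params.ideal_modulus[hyp])
                     / params.modulus_scale)]
        weights = [params.weights[0]]
        if mean_angle is not None:
            terms.append(min(1.0, abs(mean_angle - params.ideal_angle[hyp])
                             / params.angle_scale))
            weights.append(params.weights[1])
        terms.append(min(1.0, abs(spacing - params.ideal_ca_spacing)
                         / params.ca_spacing_scale))
        weights.append(params.weights[2])
        scores[hyp] = float(np.dot(terms, weights) / np.sum(weights)
                            * sum(params.weights))
    diff = abs(scores[AH] - scores[BS])
    label = _label_from_scores(scores[AH], scores[BS],
                               params.strictness_ah, params.strictness_bs)
    return CVScore(scores[AH], scores[BS], label, diff)


def _label_from_scores(s_ah: float, s_bs: float,
                       strict_ah: float, strict_bs: float) -> str:
    diff = abs(s_ah - s_bs)
    if s_ah < s_bs:
        return AH if diff > strict_ah else COIL
    if s_bs < s_ah:
        return BS if diff > strict_bs else COIL
    return COIL


def annotate_cvs(graph: CVGraph, stretches: Sequence[ConnectedStretch],
                 params: ScoringParams | None = None) -> list[CVScore]:
    """Iteratively label every CV in the graph.

    Base scores are refined for a few passes in which the labels of the
    sequence-neighbouring CVs grant a bonus (or penalty) of up to
    ``context_factor`` of the score to the matching (opposing) hypothesis;
    iteration stops at a fixed point or after ``max_iterations``.
    """
    params = params or ScoringParams()
    base = [score_cv(i, graph, stretches, params) for i in range(len(graph))]
    labels = [s.label for s in base]
    strict = {AH: params.strictness_ah, BS: params.strictness_bs}
    result = list(base)
    for _ in range(params.max_iterations):
        new_scores: list[CVScore] = []
        for i, sc in enumerate(base):
            if graph.cvs[i].degenerate:
                new_scores.append(sc)
                continue
            nb_labels = [labels[j] for j in graph.sequence_neighbours(i)]
            adj = {}
            for hyp in (AH, BS):
                same = nb_labels.count(hyp)
                other = nb_labels.count(BS if hyp == AH else AH)
                factor = 1.0 - 0.5 * params.context_factor * (same - other)
                adj[hyp] = sc.scores[hyp] * factor
            label = _label_from_scores(adj[AH], adj[BS],
                                       strict[AH], strict[BS])
            new_scores.append(CVScore(adj[AH], adj[BS], label,
                                      abs(adj[AH] - adj[BS])))
        new_labels = [s.label for s in new_scores]
        result = new_scores
        if new_labels == labels:
            break
        labels = new_labels
    return result


def residues_to_cvs(graph: CVGraph, stretches: Sequence[ConnectedStretch]
                    ) -> dict[tuple[int, int], list[int]]:
    """Map (stretch index, residue index) -> indices of covering CVs."""
    member: dict[tuple[int, int], list[int]] = {
        (si, ri): [] for si, s in enumerate(stretches)
        for ri in range(len(s))}
    for ci, cv in enumerate(graph.cvs):
        for ri in cv.window:
            member[(cv.stretch_index, ri)].append(ci)
    return member


def annotate_residues(cv_scores: Sequence[CVScore], graph: CVGraph,
                      stretches: Sequence[ConnectedStretch]
                      ) -> dict[tuple[int, int], str]:
    """Translate CV labels into one label per residue.

    Three rules, applied in order:
    (i)   a residue whose covering CVs all agree on ah or on bs gets that
          label;
    (ii)  a residue with two ah CVs, no bs CV and an ah-labelled following
          residue becomes ah;
    (iii) a residue still coil becomes bs if it joins two bs CVs and no ah
          CV, or if it joins at least one bs CV and one of the two
          preceding/following residues is coil.
    Rules (ii) and (iii) pick up fragment termini separated by short coil
    spans.  Residues covered by no CV are coil.
    """
    member = residues_to_cvs(graph, stretches)
    labels: dict[tuple[int, int], str] = {}
    # rule (i)
    for key, cvs in member.items():
        if cvs and all(cv_scores[c].label == AH for c in cvs):
            labels[key] = AH
        elif cvs and all(cv_scores[c].label == BS for c in cvs):
            labels[key] = BS
        else:
            labels[key] = COIL
    # rule (ii): needs the following residue's label; sweep C -> N
    for si, stretch in enumerate(stretches):
        for ri in range(len(stretch) - 2, -1, -1):
            key = (si, ri)
            if labels[key] != COIL:
                continue
            cvs = member[key]
            n_ah = sum(cv_scores[c].label == AH for c in cvs)
            n_bs = sum(cv_scores[c].label == BS for c in cvs)
            if n_ah >= 2 and n_bs == 0 and labels[(si, ri + 1)] == AH:
                labels[key] = AH
    # rule (iii)
    for si, stretch in enumerate(stretches):
        for ri in range(len(stretch)):
            key = (si, ri)
            if labels[key] != COIL:
                continue
            cvs = member[key]
            n_ah = sum(cv_scores[c].label == AH for c in cvs)
            n_bs = sum(cv_scores[c].label == BS for c in cvs)
            if n_bs >= 2 and n_ah == 0:
                labels[key] = BS
            elif n_bs >= 1 and n_ah == 0:
                context = [labels.get((si, rj)) for rj in
                           (ri - 2, ri - 1, ri + 1, ri + 2)
                           if (si, rj) in labels]
                if COIL in context:
                    labels[key] = BS
    return labels


@dataclasses.dataclass
class Fragment:
    """A maximal run of >= 3 residues sharing one non-coil label."""

    stretch_index: int
    start: int                  # residue index within the stretch
    stop: int                   # inclusive
    label: str
    cv_indices: list[int] = dataclasses.field(default_factory=list)
    sheet_id: int | None = None

    @property
    def n_residues(self) -> int:
        return self.stop - self.start + 1

    def residue_keys(self) -> list[tuple[int, int]]:
        return [(self.stretch_index, r) for r in range(self.start, self.stop + 1)]


def group_fragments(residue_labels: dict[tuple[int, int], str],
                    stretches: Sequence[ConnectedStretch],
                    graph: CVGraph | None = None,
                    min_len: int = 3) -> list[Fragment]:
    """Maximal same-label runs; runs shorter than ``min_len`` stay coil.

    When a graph is supplied, each fragment also collects the CVs whose
    whole window lies inside it.
    """
    fragments: list[Fragment] = []
    for si, stretch in enumerate(stretches):
        run_start = None
        run_label = COIL
        for ri in range(len(stretch) + 1):
            lab = residue_labels.get((si, ri), COIL) if ri < len(stretch) else COIL
            if lab == run_label:
                continue
            if run_label != COIL and run_start is not None:
                if ri - run_start >= min_len:
                    fragments.append(Fragment(si, run_start, ri - 1, run_label))
            run_start = ri
            run_label = lab
    if graph is not None:
        for frag in fragments:
            frag.cv_indices = [
                ci for ci, cv in enumerate(graph.cvs)
                if cv.stretch_index == frag.stretch_index
                and cv.window[0] >= frag.start and cv.window[-1] <= frag.stop]
    return fragments


def _fragment_pair_stats(a: Fragment, b: Fragment, graph: CVGraph
                         ) -> dict[str, float]:
    ii = np.array(a.cv_indices)
    jj = np.array(b.cv_indices)
    if len(ii) == 0 or len(jj) == 0:
        return {}
    ang = graph.angles[np.ix_(ii, jj)].ravel()
    dist = graph.distances[np.ix_(ii, jj)].ravel()
    ang = ang[np.isfinite(ang)]
    return {
        "angle_min": float(ang.min()) if len(ang) else float("nan"),
        "angle_max": float(ang.max()) if len(ang) else float("nan"),
        "angle_mean": float(ang.mean()) if len(ang) else float("nan"),
        "dist_min": float(dist.min()),
        "dist_max": float(dist.max()),
        "dist_mean": float(dist.mean()),
    }


def detect_sheets(fragments: list[Fragment], graph: CVGraph,
                  params: ScoringParams | None = None) -> list[Fragment]:
    """Group strands into sheets (in place) and return the fragments.

    Two strands pair when at least ``sheet_angle_fraction`` of their
    cross-fragment CV angles fall inside the parallel band or inside the
    antiparallel band, and the fragments are closer than
    ``sheet_max_distance``.  Sheets are the connected components of the
    pairing relation, so membership is transitively closed.
    """
    params = params or ScoringParams()
    strands = [f for f in fragments if f.label == BS]
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(strands)))
    for i in range(len(strands)):
        for j in range(i + 1, len(strands)):
            if strands_paired(strands[i], strands[j], graph, params):
                g.add_edge(i, j)
    for sheet_id, comp in enumerate(sorted(nx.connected_components(g),
                                           key=min)):
        for k in comp:
            strands[k].sheet_id = sheet_id
    return fragments


def strands_paired(a: Fragment, b: Fragment, graph: CVGraph,
                   params: ScoringParams | None = None) -> bool:
    params = params or ScoringParams()
    stats = _fragment_pair_stats(a, b, graph)
    if not stats:
        return False
    dist = stats["dist_min" if params.sheet_distance_stat == "min"
                 else "dist_mean"]
    if not dist < params.sheet_max_distance:
        return False
    ii, jj = np.array(a.cv_indices), np.array(b.cv_indices)
    ang = graph.angles[np.ix_(ii, jj)].ravel()
    ang = ang[np.isfinite(ang)]
    if len(ang) == 0:
        return False
    p_lo, p_hi = params.sheet_parallel_band
    a_lo, a_hi = params.sheet_antiparallel_band
    par = np.mean((ang >= p_lo) & (ang <= p_hi))
    anti = np.mean((ang >= a_lo) & (ang <= a_hi))
    return max(par, anti) >= params.sheet_angle_fraction


def build_fragment_graph(fragments: list[Fragment], graph: CVGraph,
                         params: ScoringParams | None = None):
    """Supernode graph over fragments (a ``networkx.Graph``).

    Every fragment pair is connected; the edge stores min/max/mean of all
    cross-fragment CV angles and distances and a clustering weight
    1 / mean distance, doubled (``same_type_factor``) for same-type pairs
    so that spatially close same-type elements, e.g. sheet mates, attract.
    """
    params = params or ScoringParams()
    import networkx as nx
    g = nx.Graph()
    for fi, frag in enumerate(fragments):
        g.add_node(fi, label=frag.label, stretch=frag.stretch_index,
                   start=frag.start, stop=frag.stop,
                   sheet=-1 if frag.sheet_id is None else frag.sheet_id)
    for i in range(len(fragments)):
        for j in range(i + 1, len(fragments)):
            stats = _fragment_pair_stats(fragments[i], fragments[j], graph)
            if not stats or stats["dist_mean"] <= 0:
                continue
            weight = 1.0 / stats["dist_mean"]
            if fragments[i].label == fragments[j].label:
                weight *= params.same_type_factor
            g.add_edge(i, j, weight=weight, **stats)
    return g


@dataclasses.dataclass
class AnnotatedStructure:
    """Everything the annotation stage derives from one set of stretches."""

    stretches: list[ConnectedStretch]
    graph: CVGraph
    cv_scores: list[CVScore]
    residue_labels: dict[tuple[int, int], str]
    fragments: list[Fragment]
    params: ScoringParams

    def fragment_graph(self):
        return build_fragment_graph(self.fragments, self.graph, self.params)

    def label_fraction(self, label: str) -> float:
        """Fraction of residues inside fragments of the given type."""
        total = sum(len(s) for s in self.stretches)
        if total == 0:
            return 0.0
        inside = sum(f.n_residues for f in self.fragments if f.label == label)
        return inside / total


def annotate_structure(stretches: Sequence[ConnectedStretch],
                       params: ScoringParams | None = None,
                       window: int = 3) -> AnnotatedStructure:
    """Full annotation pipeline: CVs -> graph -> CV labels -> residues ->
    fragments -> sheets."""
    params = params or ScoringParams()
    stretches = list(stretches)
    cvs = structure_cvs(stretches, window=window)
    if not cvs:
        graph = CVGraph(cvs=[], angles=np.zeros((0, 0)),
                        distances=np.zeros((0, 0)))
        return AnnotatedStructure(stretches, graph, [],
                                  {(si, ri): COIL for si, s in enumerate(stretches)
                                   for ri in range(len(s))},
                                  [], params)
    graph = build_cv_graph(cvs)
    cv_scores = annotate_cvs(graph, stretches, params)
    residue_labels = annotate_residues(cv_scores, graph, stretches)
    fragments = group_fragments(residue_labels, stretches, graph,
                                params.min_fragment_len)
    # residues dropped from sub-minimal runs go back to coil
    in_frag = {k for f in fragments for k in f.residue_keys()}
    for key in residue_labels:
        if residue_labels[key] != COIL and key not in in_frag:
            residue_labels[key] = COIL
    detect_sheets(fragments, graph, params)
    return AnnotatedStructure(stretches, graph, cv_scores, residue_labels,
                              fragments, params)


def per_residue_strictness(annotated: AnnotatedStructure,
                           path: str | Path) -> Path:
    """Write a PDB whose B column encodes annotation confidence.

    Each residue carries the maximum ``max_strictness`` (the largest
    strictness at which it would still be annotated) over its CVs, scaled
    to [0, 100]; high values mean unambiguous helix/strand geometry.
    """
    member = residues_to_cvs(annotated.graph, annotated.stretches)
    out_stretches = []
    import dataclasses as dc
    for si, stretch in enumerate(annotated.stretches):
        residues = []
        for ri, res in enumerate(stretch):
            cvs = member.get((si, ri), [])
            val = max((annotated.cv_scores[c].max_strictness for c in cvs),
                      default=0.0)
            b = float(np.clip(val, 0.0, 1.0) * 100.0)
            atoms = {n: dc.replace(a, b_factor=b) for n, a in res.atoms.items()}
            residues.append(dc.replace(res, atoms=atoms))
        out_stretches.append(ConnectedStretch(residues, stretch.provenance))
    return write_structure(out_stretches, path)


def residue_strictness_values(annotated: AnnotatedStructure) -> np.ndarray:
    """The per-residue confidence values (0-100) in flat residue order."""
    member = residues_to_cvs(annotated.graph, annotated.stretches)
    vals = []
    for si, stretch in enumerate(annotated.stretches):
        for ri in range(len(stretch)):
            cvs = member.get((si, ri), [])
            val = max((annotated.cv_scores[c].max_strictness for c in cvs),
                      default=0.0)
            vals.append(float(np.clip(val, 0.0, 1.0) * 100.0))
    return np.array(vals)


def annotation_report(annotated: AnnotatedStructure, out_dir: str | Path,
                      basename: str = "structure") -> dict[str, Path]:
    """Diagnostic curves and tables: CV moduli, consecutive-CV angles and
    consecutive CA-CA distances, as PNG plots plus CSV tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph = annotated.graph
    moduli = graph.moduli()
    cons_ang, ang_idx = [], []
    for i in range(len(graph)):
        for j in graph.sequence_neighbours(i):
            if j == i + 1:
                cons_ang.append(graph.angles[i, j])
                ang_idx.append(i)
    ca_d, ca_idx = [], []
    off = 0
    for stretch in annotated.stretches:
        ca = stretch.ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        ca_d.extend(d.tolist())
        ca_idx.extend(range(off, off + len(d)))
        off += len(stretch)

    tables = {
        "cv_moduli": pd.DataFrame({"cv_index": np.arange(len(moduli)),
                                   "modulus": moduli}),
        "consecutive_cv_angles": pd.DataFrame({"cv_index": ang_idx,
                                               "angle": cons_ang}),
        "ca_ca_distances": pd.DataFrame({"residue_index": ca_idx,
                                         "distance": ca_d}),
    }
    outputs: dict[str, Path] = {}
    for name, df in tables.items():
        csv = out_dir / f"{basename}_{name}.csv"
        df.to_csv(csv, index=False)
        outputs[f"{name}_table"] = csv
        png = out_dir / f"{basename}_{name}.png"
        fig, ax = plt.subplots(figsize=(6, 3))
        cols = df.columns
        ax.plot(df[cols[0]], df[cols[1]], marker=".", lw=1)
        ax.set_xlabel(cols[0])
        ax.set_ylabel(cols[1])
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        fig.savefig(png, dpi=100)
        plt.close(fig)
        outputs[f"{name}_plot"] = png
    return outputs
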