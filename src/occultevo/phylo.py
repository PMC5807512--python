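"""Maximum-parsimony phylogenies for gain/loss copy-number profiles.

Samples are vectors over a shared locus set with states -1 (loss),
0 (balanced) and +1 (gain).  Candidate common ancestors (intermediates)
are the shared features of every sample subset: a locus is aberrant in the
ancestor of a subset exactly when all members agree on its sign.  Directed
edges descend from the all-zero normal root through intermediates to the
observed samples; an edge may acquire new aberrations and may revert a
previously acquired gain back to balanced (a "reloss"), but may never
revert a loss, and along any root-to-sample path a relost gain may not be
regained.  Each gained locus may be relost at most twice across the whole
graph.  Among all admissible combinations of root-to-sample paths the
builder returns the directed acyclic graph(s) minimising first the total
number of genomic changes along the edges and then the number of
intermediates.

A brute-force oracle searches the restricted state lattice exhaustively
and is intended for tiny instances only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhyloVertex", "PhyloDAG", "ResourceError",
    "infer_ancestors", "admissible_edge", "admissible_edges",
    "validate_path", "build_parsimonious_dag", "brute_force_phylogeny",
    "to_dot",
]

ROOT_ID = "__root__"


class ResourceError(RuntimeError):
    """Raised when enumeration limits are exceeded; pre-filter loci or
    reduce the sample set."""


@dataclass(frozen=True)
class PhyloVertex:
    vertex_id: str
    profile: tuple[int, ...]
    level: int  # number of supporting samples (0 for the root)
    kind: str   # normal_root | intermediate | observed

    def __post_init__(self):
        if self.kind == "normal_root" and any(self.profile):
            raise ValueError("the normal root must carry no aberrations")


@dataclass
class PhyloDAG:
    vertices: dict  # vertex_id -> PhyloVertex
    edges: list[tuple[str, str]]
    paths: dict     # sample vertex_id -> root-to-leaf path (vertex ids)
    total_changes: int
    n_intermediates: int
    unique: bool = True
    n_cooptimal: int = 1

    @property
    def score(self) -> tuple[int, int]:
        return (self.total_changes, self.n_intermediates)


def _as_profiles(profiles) -> list[tuple[int, ...]]:
    out = []
    for p in profiles:
        v = tuple(int(x) for x in (p.values if hasattr(p, "values") else p))
        if any(x not in (-1, 0, 1) for x in v):
            raise ValueError("profile states must be -1, 0 or +1")
        out.append(v)
    if len({len(v) for v in out}) > 1:
        raise ValueError("profiles must share one locus set")
    return out


def _sample_ids(profiles) -> list[str]:
    ids = []
    for i, p in enumerate(profiles):
        ids.append(getattr(p, "sample_id", f"S{i}"))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    return ids


def _meet(vectors: list[tuple[int, ...]]) -> tuple[int, ...]:
    arr = np.asarray(vectors)
    first = arr[0]
    agree = np.all(arr == first, axis=0)
    return tuple(int(v) if a and v != 0 else 0 for v, a in zip(first, agree))


def infer_ancestors(profiles) -> list[PhyloVertex]:
    """Candidate ancestors: shared aberrations of every subset of size >= 2.

    A locus is aberrant in the candidate iff all subset members agree on
    its sign (opposing signs share only the balanced state).  Duplicates
    are kept once, at the highest (largest-subset) level; the all-zero
    normal root is always included.
    """
    vecs = _as_profiles(profiles)
    if len(vecs) < 2:
        raise ValueError("need at least two observed profiles")
    nloci = len(vecs[0])
    best_level: dict[tuple[int, ...], int] = {}
    for r in range(2, len(vecs) + 1):
        for subset in itertools.combinations(range(len(vecs)), r):
            m = _meet([vecs[i] for i in subset])
            if any(m):
                best_level[m] = max(best_level.get(m, 0), r)
    out = [PhyloVertex(ROOT_ID, (0,) * nloci, 0, "normal_root")]
    for i, (prof, lvl) in enumerate(
            sorted(best_level.items(), key=lambda kv: (-kv[1], kv[0]))):
        out.append(PhyloVertex(f"A{i}", prof, lvl, "intermediate"))
    return out


def admissible_edge(u: tuple[int, ...], v: tuple[int, ...]) -> bool:
    """Local admissibility of a directed edge u -> v.

    Per locus: a balanced state may change freely; an acquired gain may
    persist or be relost to balanced; a loss may never be reverted.
    """
    for a, b in zip(u, v):
        if a == -1 and b != -1:
            return False  # no regains of any losses
        if a == 1 and b == -1:
            return False  # a gain cannot flip to a loss in one event chain
    return True


def _edge_cost(u: tuple[int, ...], v: tuple[int, ...]) -> int:
    return sum(a != b for a, b in zip(u, v))


def _edge_relosses(u: tuple[int, ...], v: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(j for j, (a, b) in enumerate(zip(u, v)) if a == 1 and b == 0)


def admissible_edges(vertices: list[PhyloVertex]) -> list[tuple[str, str]]:
    """All locally admissible directed edges among a vertex set (the global
    per-path and reloss-budget conditions are enforced during assembly)."""
    ids = {v.vertex_id: v for v in vertices}
    if ROOT_ID not in ids:
        raise ValueError("vertex set must include the normal root")
    out = []
    for a in vertices:
        for b in vertices:
            if a.vertex_id == b.vertex_id or b.kind == "normal_root":
                continue
            if a.kind == "observed":
                continue  # observed samples are leaves
            if a.profile == b.profile and b.kind != "observed":
                continue
            if admissible_edge(a.profile, b.profile):
                out.append((a.vertex_id, b.vertex_id))
    return out


def validate_path(profiles: list[tuple[int, ...]]) -> tuple[bool, list[str]]:
    """Check the global constraints along a root-to-leaf profile sequence.

    Violations: any reversal of a loss, a gain flipping straight to a
    loss, regaining a relost gain, or more than one reloss of the same
    locus within the path.
    """
    if not profiles or any(profiles[0]):
        return False, ["path must start at the all-zero normal root"]
    nloci = len(profiles[0])
    relost = [0] * nloci
    violations = []
    for step, (u, v) in enumerate(zip(profiles[:-1], profiles[1:])):
        for j, (a, b) in enumerate(zip(u, v)):
            if a == -1 and b != -1:
                violations.append(f"step {step}, locus {j}: loss reverted")
            elif a == 1 and b == -1:
                violations.append(f"step {step}, locus {j}: gain -> loss")
            elif a == 1 and b == 0:
                relost[j] += 1
                if relost[j] > 1:
                    violations.append(
                        f"step {step}, locus {j}: locus relost twice in one path")
            elif a == 0 and b == 1 and relost[j]:
                violations.append(
                    f"step {step}, locus {j}: regain of a relost gain")
    return not violations, violations


# ---------------------------------------------------------------------------
# assembly


def _leaf_paths(root: tuple[int, ...], inters: list[tuple[int, ...]],
                leaf: tuple[int, ...], path_cap: int) -> list[tuple[int, ...]]:
    """All simple, globally valid paths root -> intermediates* -> leaf.

    Returned as tuples of intermediate indices (the root and leaf are
    implicit).  Paths revisiting a vertex or regaining a relost gain are
    excluded; raises ResourceError beyond ``path_cap`` paths.
    """
    nloci = len(root)
    paths: list[tuple[int, ...]] = []

    def extend(cur: tuple[int, ...], used: tuple[int, ...],
               relost: frozenset[int]) -> None:
        if admissible_edge(cur, leaf):
            if not any(leaf[j] == 1 and cur[j] != 1 and j in relost
                       for j in range(nloci)):
                paths.append(used)
                if len(paths) > path_cap:
                    raise ResourceError(
                        f"more than {path_cap} candidate paths for one sample; "
                        "pre-filter loci or reduce the sample set")
        for idx, nxt in enumerate(inters):
            if idx in used or nxt == cur:
                continue
            if not admissible_edge(cur, nxt):
                continue
            gains = [j for j in range(nloci) if cur[j] != 1 and nxt[j] == 1]
            if any(j in relost for j in gains):
                continue  # regain of a relost gain
            new_relost = relost | {j for j in range(nloci)
                                   if cur[j] == 1 and nxt[j] == 0}
            extend(nxt, used + (idx,), new_relost)

    extend(root, (), frozenset())
    return paths


def _assemble(leaves: list[tuple[int, ...]],
              inters: list[tuple[int, ...]],
              reloss_budget: int = 2,
              path_cap: int = 20_000,
              collect_all: bool = False):
    """Choose one valid path per leaf minimising (total changes along the
    union of edges, number of intermediates used).

    Returns (best_score, list of unions); each union is a list of
    (u_node, v_node) with nodes encoded as ('R',), ('I', idx) or
    ('L', leaf_idx).
    """
    nloci = len(leaves[0]) if leaves else 0
    root = (0,) * nloci

    def node_profile(node):
        kind = node[0]
        if kind == "R":
            return root
        if kind == "I":
            return inters[node[1]]
        return leaves[node[1]]

    per_leaf: list[list[list[tuple]]] = []
    for li in range(len(leaves)):
        raw = _leaf_paths(root, inters, leaves[li], path_cap)
        plist = []
        for inter_seq in raw:
            nodes = [("R",)] + [("I", i) for i in inter_seq] + [("L", li)]
            plist.append(list(zip(nodes[:-1], nodes[1:])))
        if not plist:
            raise RuntimeError("no admissible path for a sample")
        per_leaf.append(plist)

    # cheapest-first ordering inside each leaf helps the bound
    def path_cost(edges):
        return sum(_edge_cost(node_profile(u), node_profile(v)) for u, v in edges)

    for plist in per_leaf:
        plist.sort(key=path_cost)
    order = sorted(range(len(leaves)), key=lambda i: len(per_leaf[i]))

    best: dict = {"score": None, "unions": []}

    def union_score(edge_set):
        cost = 0
        used_inters = set()
        relosses = [0] * nloci
        for u, v in edge_set:
            pu, pv = node_profile(u), node_profile(v)
            cost += _edge_cost(pu, pv)
            for node in (u, v):
                if node[0] == "I":
                    used_inters.add(node[1])
            for j in _edge_relosses(pu, pv):
                relosses[j] += 1
        if any(r > reloss_budget for r in relosses):
            return None
        return (cost, len(used_inters))

    def dfs(pos: int, edge_set: frozenset, cost_so_far: int):
        if best["score"] is not None and cost_so_far > best["score"][0]:
            return
        if pos == len(order):
            score = union_score(edge_set)
            if score is None:
                return
            if best["score"] is None or score < best["score"]:
                best["score"] = score
                best["unions"] = [sorted(edge_set)]
            elif collect_all and score == best["score"]:
                if sorted(edge_set) not in best["unions"]:
                    best["unions"].append(sorted(edge_set))
            return
        li = order[pos]
        for edges in per_leaf[li]:
            new_set = edge_set | frozenset(edges)
            extra = sum(_edge_cost(node_profile(u), node_profile(v))
                        for u, v in set(edges) - edge_set)
            dfs(pos + 1, new_set, cost_so_far + extra)

    dfs(0, frozenset(), 0)
    if best["score"] is None:
        raise RuntimeError("no admissible DAG found")
    return best["score"], best["unions"], node_profile


def build_parsimonious_dag(profiles, all_optima: bool = False,
                           max_samples: int = 8, max_loci: int = 60,
                           path_cap: int = 20_000) -> PhyloDAG:
    """Assemble the maximum-parsimony DAG for a set of observed profiles.

    Candidate intermediates are the inferred common ancestors; among all
    admissible path combinations the DAG minimising (total changes,
    intermediate count) is returned, with deterministic selection among
    co-optima by lexicographic order of the sorted vertex profiles.  The
    ``unique`` flag reports whether the optimum was unique.
    """
    vecs = _as_profiles(profiles)
    ids = _sample_ids(profiles)
    if len(vecs) > max_samples or len(vecs[0]) > max_loci:
        raise ResourceError(
            f"instance exceeds enumeration limits ({max_samples} samples, "
            f"{max_loci} loci); pre-filter variable loci first")
    nloci = len(vecs[0])
    root = (0,) * nloci

    if len(vecs) == 1:
        anc = [PhyloVertex(ROOT_ID, root, 0, "normal_root")]
        inters: list[tuple[int, ...]] = []
        levels: dict[tuple[int, ...], int] = {}
    else:
        anc = infer_ancestors(profiles)
        inters = [v.profile for v in anc if v.kind == "intermediate"]
        levels = {v.profile: v.level for v in anc if v.kind == "intermediate"}

    score, unions, node_profile = _assemble(
        vecs, inters, path_cap=path_cap, collect_all=True)

    def union_key(u):
        return sorted((node_profile(a), node_profile(b)) for a, b in u)

    unions.sort(key=union_key)
    chosen = unions[0]

    vertices = {ROOT_ID: PhyloVertex(ROOT_ID, root, 0, "normal_root")}
    edges = []
    id_of = {("R",): ROOT_ID}
    for li, sid in enumerate(ids):
        id_of[("L", li)] = sid
        vertices[sid] = PhyloVertex(sid, vecs[li], 1, "observed")
    for u, v in chosen:
        for node in (u, v):
            if node[0] == "I" and node not in id_of:
                prof = inters[node[1]]
                vid = f"A{node[1]}"
                id_of[node] = vid
                vertices[vid] = PhyloVertex(vid, prof, levels.get(prof, 2),
                                            "intermediate")
    for u, v in chosen:
        edges.append((id_of[u], id_of[v]))

    # per-sample root-to-leaf paths recovered from the chosen union
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    paths = {}
    for sid in ids:
        stack = [[ROOT_ID]]
        found = None
        while stack:
            p = stack.pop()
            if p[-1] == sid:
                found = p
                break
            for nxt in sorted(adj.get(p[-1], [])):
                if nxt not in p:
                    stack.append(p + [nxt])
        paths[sid] = found

    dag = PhyloDAG(vertices=vertices, edges=edges, paths=paths,
                   total_changes=score[0], n_intermediates=score[1],
                   unique=(len(unions) == 1), n_cooptimal=len(unions))
    if not all_optima:
        dag.meta_all = None
    else:
        dag.meta_all = unions
    return dag


def brute_force_phylogeny(profiles, max_samples: int = 4,
                          max_loci: int = 6) -> tuple[int, int]:
    """Exhaustive global optimum (total changes, intermediates) over the
    restricted state lattice; tiny instances only.

    Candidate intermediate profiles are every lattice point whose state at
    each locus is balanced or one of the states observed there (ancestors
    carrying aberrations absent from every sample can only add changes).
    All intermediate subsets up to one less than the number of samples are
    tried; the search stops early once the lower bound - one change per
    distinct observed (locus, state) aberration - is attained.
    """
    vecs = _as_profiles(profiles)
    if len(vecs) > max_samples or len(vecs[0]) > max_loci:
        raise ResourceError("instance above brute-force limits")
    nloci = len(vecs[0])
    root = (0,) * nloci

    if len(vecs) == 1:
        return sum(v != 0 for v in vecs[0]), 0

    states_per_locus = [sorted({0} | {v[j] for v in vecs})
                        for j in range(nloci)]
    lattice = [p for p in itertools.product(*states_per_locus) if any(p)]
    # an intermediate is useful only if some sample is reachable from it
    lattice = [p for p in lattice
               if sum(admissible_edge(p, v) for v in vecs) >= 2]

    lower = len({(j, v[j]) for v in vecs for j in range(nloci) if v[j] != 0})

    best: tuple[int, int] | None = None
    for k in range(0, len(vecs)):
        for subset in itertools.combinations(lattice, k):
            try:
                score, _, _ = _assemble(vecs, list(subset), path_cap=50_000)
            except RuntimeError:
                continue
            if best is None or score < best:
                best = score
        if best is not None and best[0] <= lower:
            break
    if best is None:
        raise RuntimeError("no admissible phylogeny found")
    return best


def to_dot(dag: PhyloDAG) -> str:
    """DOT export with profile digests; the square-root aberration-count
    ordinate used in tree figures is attached as a vertex attribute."""
    lines = ["digraph phylogeny {", "  rankdir=TB;"]
    for vid, v in dag.vertices.items():
        nab = sum(x != 0 for x in v.profile)
        digest = "".join("+" if x == 1 else "-" if x == -1 else "." for x in v.profile)
        lines.append(
            f'  "{vid}" [label="{vid}\\n{digest}", kind="{v.kind}", '
            f'level="{v.level}", sqrt_aberrations="{nab ** 0.5:.3f}"];')
    for u, v in dag.edges:
        cost = _edge_cost(dag.vertices[u].profile, dag.vertices[v].profile)
        lines.append(f'  "{u}" -> "{v}" [label="{cost}"];')
    lines.append("}")
    return "\n".join(lines)
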