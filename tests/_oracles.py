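"""Independent oracles shared across test modules.

Each oracle re-derives the quantity it checks by a different route than the
implementation: exhaustive enumeration for uORFs, the BM covariance matrix
for contrasts, naive recounts elsewhere.
"""

import dendropy
import numpy as np

from utrscape.phylo_contrasts import compute_contrasts, parse_newick

STOPS = {"TAA", "TAG", "TGA"}


def oracle_uorfs(seq: str, min_len: int = 9) -> list[tuple[int, int, int]]:
    """Enumerate every ATG with its first in-frame stop, deduplicate per stop
    keeping the earliest ATG, then filter by minimum length."""
    s = seq.upper().replace("U", "T")
    out = []
    for f in range(3):
        stops = [p for p in range(f, len(s) - 2, 3) if s[p : p + 3] in STOPS]
        atgs = [p for p in range(f, len(s) - 2, 3) if s[p : p + 3] == "ATG"]
        by_stop: dict[int, int] = {}
        for a in atgs:  # ascending, so setdefault keeps the first uAUG
            nxt = [q for q in stops if q > a]
            if nxt:
                by_stop.setdefault(nxt[0], a)
        for q, a in by_stop.items():
            if q + 3 - a >= min_len:
                out.append((f, a, q + 3))
    return sorted(out, key=lambda t: (t[1], t[0]))


def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def bm_covariance(newick: str) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance V_ij = depth of the MRCA of tips i, j,
    from patristic and root distances (independent of the pruning pass)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    tree.calc_node_root_distances()
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    droot = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    n = len(taxa)
    V = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            d = 0.0 if i == j else pdm.patristic_distance(ti, tj)
            V[i, j] = (droot[ti.label] + droot[tj.label] - d) / 2.0
    return [t.label for t in taxa], V


def contrast_matrix(newick: str, labels: list[str]) -> np.ndarray:
    """Contrasts are linear in the trait vector; extract the linear map by
    applying the implementation to unit traits."""
    cols = []
    for lab in labels:
        trait = {l: float(l == lab) for l in labels}
        cols.append(compute_contrasts(parse_newick(newick), trait).values)
    return np.array(cols).T
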