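"""Random GPR tree generation and an independent brute-force evaluator."""

from __future__ import annotations

from itertools import product

from phifba.model_io import GPRTree


def random_gpr_tree(rng, max_leaves: int = 15, _counter=None) -> GPRTree:
    """Random boolean tree with at most ``max_leaves`` distinct gene leaves.

    Trees are in the canonical alternating form (no AND child of an AND,
    no OR child of an OR) — the form the associative-flattening parser
    round-trips exactly.
    """
    if _counter is None:
        _counter = [0]

    def build(budget: int, parent: str | None) -> GPRTree:
        if budget <= 1 or rng.random() < 0.35:
            _counter[0] += 1
            return GPRTree(kind="gene", gene=f"g{_counter[0]}")
        if parent is None:
            kind = "and" if rng.random() < 0.5 else "or"
        else:
            kind = "or" if parent == "and" else "and"
        n_children = int(rng.integers(2, min(4, budget) + 1))
        share = budget // n_children
        children = tuple(build(max(1, share), kind) for _ in range(n_children))
        return GPRTree(kind=kind, children=children)

    return build(max_leaves, None)


def dnf_weight(tree: GPRTree, weights: dict) -> float:
    """Brute-force reaction weight via disjunctive normal form.

    Expands the tree into its full set of AND-conjunctions (all
    distributions of OR over AND) and takes max over conjunctions of min
    over genes — an evaluation path independent of the recursive fold.
    """
    def conjunctions(node) -> list:
        if node.kind == "gene":
            return [frozenset([node.gene])]
        if node.kind == "or":
            out = []
            for child in node.children:
                out.extend(conjunctions(child))
            return out
        # AND: cartesian product of children's conjunction sets
        out = []
        for combo in product(*(conjunctions(c) for c in node.children)):
            out.append(frozenset().union(*combo))
        return out

    return max(min(weights[g] for g in conj) for conj in conjunctions(tree))


def truth_eval(tree: GPRTree, present: dict) -> bool:
    """Boolean evaluation (for checking min/max degenerates to and/or)."""
    if tree.kind == "gene":
        return present[tree.gene]
    vals = [truth_eval(c, present) for c in tree.children]
    return all(vals) if tree.kind == "and" else any(vals)
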