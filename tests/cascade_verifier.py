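"""Independent brute-force verifier for connector placement, shared by the
cascade unit tests and the acceptance suite. It re-derives everything from
the enrichment table, clustering and knowledge base with plain loops,
independent of the graph-assembly code path."""
import pandas as pd


def brute_force_connectors(clustering, enrichment: pd.DataFrame, kb,
                           alpha: float = 0.05) -> set:
    """Enumerate (TF, cluster I, cluster II) triples satisfying: TF is DE in
    cluster I (a clustered member), a knowledge-base target of a TF upstream
    of cluster I, and enriched in cluster II — with the TF-TF retention rule
    recomputed from scratch."""
    targets = {tf: set(grp["tg"]) for tf, grp in kb.edges.groupby("tf")}
    tfs = set(targets)
    enriched: dict[str, set[int]] = {}
    for _, r in enrichment.iterrows():
        if r["p"] < alpha:
            enriched.setdefault(str(r["tf"]), set()).add(int(r["cluster"]))
    member = {tf: int(clustering.assignment[tf]) for tf in tfs
              if tf in clustering.assignment.index}
    retained = set()
    for a, clusters_a in enriched.items():
        for b in targets[a]:
            if b == a or b not in tfs:
                continue
            if b in member and member[b] in clusters_a:
                retained.add(a)
                retained.add(b)
    found = set()
    for b in tfs:
        if b not in member or b not in retained:
            continue
        ci = member[b]
        has_parent = any(
            ci in enriched.get(a, set()) and a in retained and b in targets[a]
            and a != b
            for a in tfs)
        if not has_parent:
            continue
        for cii in enriched.get(b, set()):
            if cii != ci:
                found.add((b, ci, cii))
    return found
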