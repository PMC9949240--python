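"""Independent brute-force oracles kept free of the implementation under test."""


def indel_ratio_oracle(a: str, b: str) -> float:
    """Indel similarity via the full edit-distance DP (sub cost 2)."""
    la, lb = len(a), len(b)
    if la + lb == 0:
        return 100.0
    dist = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dist[i][0] = i
    for j in range(lb + 1):
        dist[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = dist[i - 1][j - 1] + (0 if a[i - 1] == b[j - 1] else 2)
            dist[i][j] = min(dist[i - 1][j] + 1, dist[i][j - 1] + 1, sub)
    return 100.0 * (1.0 - dist[la][lb] / (la + lb))


def count_sentences_oracle(entity) -> dict:
    """Expected verbalized-sentence counts per source kind for one entity,
    under the merge-synonyms-into-first-relation rule."""
    iupac = {"IUPAC_NAME", "IUPAC NAME", "IUPAC"}
    mergeable = sum(1 for _, t in entity.synonyms if t not in iupac)
    standalone = sum(1 for _, t in entity.synonyms if t in iupac)
    n_rel = len(entity.relations)
    counts = {"triple": 0, "synonym": 0, "definition": 0, "merged": 0}
    if n_rel and mergeable:
        counts["merged"] = 1
        counts["triple"] = n_rel - 1
    else:
        counts["triple"] = n_rel
        counts["synonym"] += mergeable
    counts["synonym"] += standalone
    if entity.definition:
        counts["definition"] = 1
    return counts
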