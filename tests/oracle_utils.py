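"""Brute-force reference classifier used to cross-check the indexed matcher.

Scans the raw record collection directly with nested loops — no GeneIndex —
reproducing the tier semantics from first principles. Deliberately slow and
obvious so disagreements indict the indexed implementation.
"""

from genealias.normalizer import canonical_key, variants

MIN_SUBSTRING_LEN = 2


def brute_classify(term, records, prior_terms):
    """Return (match_type_name, gene_id, duplicate_of, suggestion_gene_ids)."""
    folded = term.casefold()
    for i, prior in enumerate(prior_terms):
        if prior.casefold() == folded:
            return ("DUPLICATE", None, i, ())

    for r in records:
        if term == r.symbol:
            return ("EXACT", r.gene_id, None, ())
    for r in records:
        if term == str(r.gene_id):
            return ("EXACT", r.gene_id, None, ())
        for values in r.dbxrefs.values():
            for v in values:
                if term == v:
                    return ("EXACT", r.gene_id, None, ())
                if ":" in v and term == v.rsplit(":", 1)[1]:
                    return ("EXACT", r.gene_id, None, ())

    tv = variants(term)
    symbol_hits = []
    for v in tv.variants[1:]:
        k = canonical_key(v)
        for r in records:
            if canonical_key(r.symbol) == k and r.gene_id not in symbol_hits:
                symbol_hits.append(r.gene_id)
    if len(symbol_hits) == 1:
        return ("AUTO_ACCEPTED", symbol_hits[0], None, ())

    usable = [v.casefold() for v in tv.variants if len(v) >= MIN_SUBSTRING_LEN]
    best = {}
    for r in records:
        targets = [r.symbol] + list(r.synonyms)
        for target in targets:
            tf = target.casefold()
            matched = exact = False
            for v in usable:
                if v in tf:
                    matched = True
                    if v == tf:
                        exact = True
            if not matched:
                continue
            key = (not exact, len(target), target)
            if r.gene_id not in best or key < best[r.gene_id]:
                best[r.gene_id] = key
    if best:
        order = sorted(best, key=lambda g: (best[g][0], best[g][1], g))
        return ("SUGGESTION_PENDING", None, None, tuple(order))

    return ("NO_MATCH", None, None, ())


def random_queries(rng, records, n):
    """Draw n query strings biased toward interesting collisions: verbatim
    symbols/synonyms/identifiers, case changes, fragments, hyphen insertions,
    and junk."""
    pool = []
    for r in records:
        pool.append(r.symbol)
        pool.extend(r.synonyms)
        pool.append(str(r.gene_id))
        for values in r.dbxrefs.values():
            pool.extend(values)
    queries = []
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    for _ in range(n):
        mode = rng.random()
        base = rng.choice(pool)
        if mode < 0.35:
            q = base
        elif mode < 0.55:
            q = base.lower()
        elif mode < 0.70:
            q = base[: max(2, len(base) // 2)]
        elif mode < 0.85:
            cut = rng.randrange(1, max(2, len(base)))
            q = base[:cut] + "-" + base[cut:]
        else:
            q = "".join(rng.choices(letters, k=rng.randint(2, 8)))
        queries.append(q)
    return queries
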