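"""Independent brute-force reference implementation for tests.

Works on plain tuples and dicts, never on package internals, so it can
serve as an oracle for the pipeline: harmonization by explicit scans,
genus lookup by explicit parent-chain walks, counts by triple loops over
diseases × strains × metabolites.
"""

from __future__ import annotations


def oracle_genus(taxid, parent, rank):
    """Walk the parent chain to the first genus-rank ancestor (inclusive)."""
    seen = set()
    cur = taxid
    while cur not in seen:
        seen.add(cur)
        if rank[cur] == "genus":
            return cur
        nxt = parent[cur]
        if nxt == cur:
            return None
        cur = nxt
    return None


def oracle_harmonize(dm_rows):
    """Deduplicate (disease, taxid, direction) rows, drop both-direction pairs."""
    deduped = list(dict.fromkeys(dm_rows))
    dirs = {}
    for d, t, direc in deduped:
        dirs.setdefault((d, t), set()).add(direc)
    bad = {pair for pair, ds in dirs.items() if len(ds) > 1}
    return [(d, t, direc) for d, t, direc in deduped if (d, t) not in bad]


def oracle_score(dm_rows, mm_rows, parent, rank):
    """Score every (disease, metabolite) pair with m+n >= 1.

    dm_rows: (disease_id, genus_taxid, "increase"|"decrease") tuples.
    mm_rows: (strain_taxid, metabolite_cid) tuples.
    Returns {(disease, cid): (m, n, M, N, s_as, s_ac)}.
    """
    dm = oracle_harmonize(dm_rows)
    mm = list(dict.fromkeys(mm_rows))
    universe = sorted({t for t, _ in mm})
    diseases = sorted({d for d, _, _ in dm})
    metabolites = sorted({c for _, c in mm})

    genus_dir = {}
    for d, t, direc in dm:
        g = oracle_genus(t, parent, rank) if t in parent else None
        if g is None:
            continue
        genus_dir[(d, g)] = direc

    out = {}
    for d in diseases:
        inc, dec = set(), set()
        for s in universe:
            if s not in parent:
                continue
            g = oracle_genus(s, parent, rank)
            direc = genus_dir.get((d, g))
            if direc == "increase":
                inc.add(s)
            elif direc == "decrease":
                dec.add(s)
        M, N = len(inc), len(dec)
        for c in metabolites:
            producers = {t for t, cc in mm if cc == c}
            m = len(producers & inc)
            n = len(producers & dec)
            if m + n == 0:
                continue
            s_as = (m / M if M else 0.0) - (n / N if N else 0.0)
            s_ac = (m + n) * abs(s_as)
            out[(d, c)] = (m, n, M, N, s_as, s_ac)
    return out


def random_instance(rng, max_diseases=5, max_genera=6, max_strains=20, max_metabolites=30):
    """Draw a random small instance as raw tuples plus parent/rank maps.

    Disease–microbe rows may contain duplicates and contradictions so the
    harmonization path is exercised too.
    """
    n_dis = int(rng.integers(1, max_diseases + 1))
    n_gen = int(rng.integers(1, max_genera + 1))
    n_str = int(rng.integers(1, max_strains + 1))
    n_met = int(rng.integers(1, max_metabolites + 1))

    parent = {1: 1}
    rank = {1: "no rank"}
    genera = []
    for g in range(n_gen):
        taxid = 10 + g
        genera.append(taxid)
        parent[taxid] = 1
        rank[taxid] = "genus"
    strains = []
    for s in range(n_str):
        taxid = 1000 + s
        strains.append(taxid)
        parent[taxid] = genera[int(rng.integers(0, n_gen))]
        rank[taxid] = "strain"

    diseases = [f"D{i + 1:06d}" for i in range(n_dis)]
    dm_rows = []
    for d in diseases:
        for g in genera:
            r = rng.random()
            if r < 0.35:
                dm_rows.append((d, g, "increase"))
            elif r < 0.7:
                dm_rows.append((d, g, "decrease"))
            if rng.random() < 0.1:  # duplicate or contradiction
                dm_rows.append((d, g, "increase" if rng.random() < 0.5 else "decrease"))

    mm_rows = []
    for s in strains:
        for c in range(1, n_met + 1):
            if rng.random() < 0.2:
                mm_rows.append((s, c))
    return dm_rows, mm_rows, parent, rank
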