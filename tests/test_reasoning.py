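"""Part-of closure, causal sign composition, pattern queries."""

import itertools
import random

import pytest

from cencam import fixtures
from cencam.errors import CencamError, OntologyError
from cencam.model import CeNCAMModel, Evidence
from cencam.reasoning import (
    Pattern,
    PatternEdge,
    PatternNode,
    causal_sign,
    net_effect,
    part_of_closure,
    query,
)

EV = (Evidence("ECO:0000059", "test"),)


# -- part_of closure ---------------------------------------------------------


def _random_partof_model(index, seed, n=20, p_edge=0.15):
    """Random part_of DAG over biological-process instances."""
    rng = random.Random(seed)
    m = CeNCAMModel(f"po-{seed}", index=index)
    ids = [m.add_individual("GO:0009987") for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            m.assert_edge(ids[i], "BFO:0000050", ids[j], EV)
    return m, ids


def _reachable(pairs, n_ids):
    """Brute-force reachability over explicit edge pairs."""
    adj = {}
    for s, o in pairs:
        adj.setdefault(s, set()).add(o)
    out = set()
    for s in n_ids:
        stack = list(adj.get(s, ()))
        seen = set()
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(adj.get(cur, ()))
        out |= {(s, t) for t in seen}
    return out


def test_closure_on_transitive_chain(index, worked):
    m = worked["fig3a"]
    derived = part_of_closure(m)
    pairs = {(m.class_of(a.subject), m.class_of(a.object)) for a in derived}
    # the signaling pathway reaches the behavior without a written edge
    assert ("GO:0098664", "GO:0018991") in pairs
    assert all(a.provenance == "derived" for a in derived)


def test_closure_empty_without_part_of(index):
    m = CeNCAMModel("m", index=index)
    a = m.add_individual("GO:0051899")
    b = m.add_individual("GO:0051899")
    m.assert_edge(a, "RO:0002304", b, EV)
    assert part_of_closure(m) == []


def test_closure_matches_reachability_oracle_and_is_idempotent(index):
    for seed in range(15):
        m, ids = _random_partof_model(index, seed)
        direct = {(a.subject, a.object) for a in m.asserted()
                  if a.relation == "BFO:0000050"}
        derived = part_of_closure(m)
        got = {(a.subject, a.object) for a in derived}
        assert got == _reachable(direct, ids) - direct
        assert part_of_closure(m) == []  # idempotent


def test_closure_invariant_under_edge_order(index):
    m1, _ = _random_partof_model(index, 42)
    m2 = CeNCAMModel.from_dict(m1.to_dict(), index)
    random.Random(0).shuffle(m2.assertions)
    d1 = {(a.subject, a.object) for a in part_of_closure(m1)}
    d2 = {(a.subject, a.object) for a in part_of_closure(m2)}
    assert d1 == d2


# -- causal sign -------------------------------------------------------------


def test_causal_sign_values(index):
    assert causal_sign("RO:0002213", index) == 1
    assert causal_sign("RO:0002304", index) == 1
    assert causal_sign("RO:0002212", index) == -1
    assert causal_sign("RO:0002305", index) == -1
    assert causal_sign("RO:0002418", index) == 0
    assert causal_sign("BFO:0000050", index) == 0  # mereology carries no sign


def test_causal_sign_undefined_for_location(index):
    with pytest.raises(OntologyError):
        causal_sign("BFO:0000066", index)


def test_sign_equals_nearest_signed_ancestor(index):
    """Hierarchy-walk oracle: a causal relation's sign equals the sign of
    the nearest ancestor that carries one."""
    def nearest(rel, depth=0):
        r = index.relation(rel)
        if r.sign != 0 or not r.parents:
            return r.sign
        return nearest(r.parents[0], depth + 1)

    for c, r in index.relations.items():
        if r.category == "causal" and r.sign != 0:
            assert causal_sign(c, index) == nearest(c)


# -- net effect --------------------------------------------------------------


def _oracle_net_effect(model, index, source, target, cap=12):
    """Independent exhaustive path enumeration with its own sign algebra."""
    edges = []
    for a in model.asserted():
        r = index.relation(a.relation)
        if r.category == "causal":
            edges.append((a.subject, a.object, r.sign if r.sign else None))
        elif a.relation == "BFO:0000050":
            edges.append((a.subject, a.object, 1))
    if source == target:
        return "positive"
    values = []

    def dfs(node, visited, prod, unknown, depth):
        if depth > cap:
            return
        for s, o, sign in edges:
            if s != node or o in visited:
                continue
            u = unknown or sign is None
            p = prod * (sign if sign is not None else 1)
            if o == target:
                values.append("unknown" if u else
                              ("positive" if p > 0 else "negative"))
            else:
                dfs(o, visited | {o}, p, u, depth + 1)

    dfs(source, {source}, 1, False, 0)
    if not values:
        return "none"
    vs = set(values)
    if {"positive", "negative"} <= vs:
        return "ambiguous"
    if "unknown" in vs:
        return "unknown"
    return vs.pop()


def test_net_effect_source_equals_target(index):
    m = CeNCAMModel("m", index=index)
    a = m.add_individual("GO:0051899")
    r = net_effect(m, a, a, index)
    assert r.value == "positive" and r.paths == ((),)


def test_net_effect_sign_algebra_on_chain(index):
    m = CeNCAMModel("m", index=index)
    a = m.add_individual("GO:0051899")
    b = m.add_individual("GO:0051899")
    c = m.add_individual("GO:0051899")
    m.assert_edge(a, "RO:0002304", b, EV)
    m.assert_edge(b, "RO:0002305", c, EV)
    assert net_effect(m, a, c, index).value == "negative"


def test_net_effect_unknown_and_ambiguous(index):
    m = CeNCAMModel("m", index=index)
    a, b, c = (m.add_individual("GO:0051899") for _ in range(3))
    m.assert_edge(a, "RO:0002418", b, EV)   # agnostic sign
    m.assert_edge(b, "RO:0002304", c, EV)
    assert net_effect(m, a, c, index).value == "unknown"
    # add a decisive disagreement: two parallel signed routes
    d = m.add_individual("GO:0051899")
    m.assert_edge(a, "RO:0002304", d, EV)
    m.assert_edge(d, "RO:0002304", c, EV)
    e = m.add_individual("GO:0051899")
    m.assert_edge(a, "RO:0002305", e, EV)
    m.assert_edge(e, "RO:0002304", c, EV)
    assert net_effect(m, a, c, index).value == "ambiguous"


def test_net_effect_fig5_matches_oracle(index, worked):
    m = worked["fig5"]
    for s in m.individuals:
        for t in m.individuals:
            assert net_effect(m, s, t, index).value == \
                _oracle_net_effect(m, index, s, t), (s, t)


def test_net_effect_random_models_match_oracle(index):
    for seed in range(20):
        m, _ = fixtures.random_model(seed, 12, 24, 0.0)
        ids = sorted(m.individuals)
        rng = random.Random(seed)
        for _ in range(15):
            s, t = rng.choice(ids), rng.choice(ids)
            assert net_effect(m, s, t, index).value == \
                _oracle_net_effect(m, index, s, t)


def test_specializing_agnostic_edge_never_flips_sign(index):
    """Replacing a sign-0 causal edge with positively-regulates can turn
    unknown into positive but never positive into negative (monotone
    information gain)."""
    for seed in range(20):
        m, _ = fixtures.random_model(seed + 100, 10, 18, 0.0)
        agnostic = [i for i, a in enumerate(m.assertions)
                    if a.relation in ("RO:0002418", "RO:0002411")]
        if not agnostic:
            continue
        i = agnostic[0]
        a = m.assertions[i]
        before = {}
        ids = sorted(m.individuals)
        for s in ids[:6]:
            for t in ids[:6]:
                before[(s, t)] = net_effect(m, s, t, index).value
        m.assertions[i] = type(a)(a.assertion_id, a.subject, "RO:0002213",
                                  a.object, a.evidence, a.provenance, a.sources)
        for (s, t), old in before.items():
            new = net_effect(m, s, t, index).value
            if old == "positive":
                assert new in ("positive", "ambiguous")
            if old == "negative":
                assert new in ("negative", "ambiguous")
            assert not (old == "positive" and new == "negative")
            assert not (old == "negative" and new == "positive")


# -- pattern queries ---------------------------------------------------------


def _peptidergic_model(index):
    m = CeNCAMModel("pep", index=index)
    p_ash = m.add_individual("GO:0009987")
    ash = m.add_individual("CeNCAM:ASH_neuron")
    sig = m.add_individual("CeNCAM:neuron_to_neuron_extra_synaptic_peptide_signaling")
    dep = m.add_individual("GO:0051899")
    ria = m.add_individual("CeNCAM:RIA_neuron")
    m.assert_edge(p_ash, "BFO:0000066", ash, EV)
    m.assert_edge(p_ash, "RO:0002418", sig, EV)
    m.assert_edge(sig, "RO:0002418", dep, EV)
    m.assert_edge(dep, "BFO:0000066", ria, EV)
    return m, ria


def _receiving_pattern():
    return Pattern(
        nodes=(PatternNode("sig", "CeNCAM:neuron_to_neuron_extra_synaptic_peptide_signaling"),
               PatternNode("proc", "GO:0009987"),
               PatternNode("neuron", "CeNCAM:neuron")),
        edges=(PatternEdge("sig", "RO:0002418", "proc"),
               PatternEdge("proc", "BFO:0000066", "neuron")),
        answer="neuron",
    )


def test_query_finds_peptidergic_target(index):
    m, ria = _peptidergic_model(index)
    results = query(m, _receiving_pattern(), index)
    assert [b["neuron"] for b in results] == [ria]


def test_query_no_match_is_empty(index):
    m = CeNCAMModel("m", index=index)
    m.add_individual("GO:0051899")
    pat = Pattern((PatternNode("x", "CHEBI:24431"),), (), "x")
    assert query(m, pat, index) == []


def test_query_stable_under_disconnected_additions(index):
    m, ria = _peptidergic_model(index)
    before = query(m, _receiving_pattern(), index)
    m.add_individual("CHEBI:28790")
    m.add_individual("GO:0018991")
    assert query(m, _receiving_pattern(), index) == before


def test_query_matches_bruteforce_assignment_oracle(index):
    rng = random.Random(3)
    for seed in range(10):
        m, _ = fixtures.random_model(seed + 50, 10, 20, 0.0)
        classes = [m.class_of(i) for i in sorted(m.individuals)]
        n_vars = rng.randint(2, 3)
        # build a connected random pattern from existing edges
        asserted = m.asserted()
        if len(asserted) < n_vars - 1:
            continue
        a = rng.choice(asserted)
        pat = Pattern(
            nodes=(PatternNode("v0", m.class_of(a.subject)),
                   PatternNode("v1", m.class_of(a.object))),
            edges=(PatternEdge("v0", a.relation, "v1"),),
            answer="v0",
        )
        got = {tuple(sorted(b.items())) for b in query(m, pat, index)}
        # oracle: all injective assignments checked directly
        ids = sorted(m.individuals)
        expect = set()
        for x in ids:
            for y in ids:
                if x == y:
                    continue
                if not index.is_descendant(m.class_of(x), m.class_of(a.subject)):
                    continue
                if not index.is_descendant(m.class_of(y), m.class_of(a.object)):
                    continue
                ok = any(aa.subject == x and aa.object == y
                         and index.relation_descends(aa.relation, a.relation)
                         for aa in m.assertions)
                if ok:
                    expect.add((("v0", x), ("v1", y)))
        assert got == expect


def test_pattern_must_be_connected_and_name_its_answer():
    with pytest.raises(CencamError):
        Pattern((PatternNode("a", "GO:0009987"),
                 PatternNode("b", "GO:0009987")), (), "a")
    with pytest.raises(CencamError):
        Pattern((PatternNode("a", "GO:0009987"),), (), "missing")
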