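"""Self-contained test substrate.

* :func:`builtin_ontology` — the embedded mini-ontology (a hand-built subset
  of GO/WBbt/ChEBI/ECO/ECTO/PATO plus the proposed classes).
* :func:`worked_example` — the twelve worked-example circuit models (egg
  laying and CO2 avoidance), each validating with zero errors.  The
  single-statement examples are built by instantiating their statement
  template; the compiled/complex examples are built directly.
* :func:`fixture_connectome` / :func:`overlay_models` — the mini-connectome
  and the per-neuron functional models behind the annotated-connectome
  example.
* :func:`random_model` / :func:`random_statement_table` — seeded generators
  for property tests, returning their planted ground truth alongside.

Every CURIE used by any fixture resolves in the builtin ontology (the
catalog is closed), and the generators are pure functions of their seed.
"""

from __future__ import annotations

import random
from functools import lru_cache
from importlib import resources

from .errors import CencamError
from .io import (
    CurationStats,
    StatementRecord,
    read_statement_table,
    statement_stats,
    write_statement_table,
)
from .model import CeNCAMModel, Evidence
from .ontology import OntologyIndex, load_obo_subset
from . import templates as _templates

# frequently used classes
GO = {
    "cellular_process": "GO:0009987",
    "depolarization": "GO:0051899",
    "nervous_system_process": "GO:0050877",
    "behavior": "GO:0007610",
    "egg_laying": "GO:0018991",
    "synaptic_transmission": "GO:0007268",
    "signal_transduction": "GO:0007165",
}
ECO_EXP = "ECO:0000059"
ECO_OPTO = "ECO:0006033"
ECO_SYNINHIB = "CeNCAM:synaptic_transmission_inhibition_evidence"

HSN = "WBbt:0006830"
UV1 = "WBbt:0006791"
VM = "WBbt:0006917"
VC = "CeNCAM:VC_neuron"
AWC = "CeNCAM:AWC_neuron"
BAG = "CeNCAM:BAG_neuron"
AFD = "CeNCAM:AFD_neuron"
ASH = "CeNCAM:ASH_neuron"
URX = "CeNCAM:URX_neuron"
RIA = "CeNCAM:RIA_neuron"

CO2 = "CHEBI:16526"
SEROTONIN = "CHEBI:28790"

POS_REG_EGG = "CeNCAM:positive_regulation_of_egg_deposition"
NEG_REG_EGG = "CeNCAM:negative_regulation_of_egg_deposition"
CO2_RESPONSE = "CeNCAM:behavioral_response_to_carbon_dioxide"
CO2_AVOIDANCE = "CeNCAM:carbon_dioxide_avoidance_behavior"
SIGNAL_INTEGRATION = "CeNCAM:signal_integration_process"
BEHAVIOR_COORD = "CeNCAM:behavior_co_ordination_process"

FIXTURE_MODEL_NAMES = (
    "fig2a", "fig2b", "fig2c", "fig3a", "fig3b", "fig3c",
    "fig4a", "fig4b", "fig4c", "fig5", "fig6c", "fig6d",
)


@lru_cache(maxsize=1)
def builtin_ontology() -> OntologyIndex:
    """Load the embedded fixture ontology (cached; treat as read-only)."""
    text = (resources.files("cencam") / "data" / "fixture_ontology.obo").read_text()
    return load_obo_subset(text)


def _ev(reference: str, eco: str = ECO_EXP) -> tuple[Evidence, ...]:
    return (Evidence(eco, reference),)


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

#: template assignment for the single-statement worked examples (the
#: compiled/complex figures have no single-template shape and map to None).
ASSIGNED_TEMPLATES: dict[str, tuple[str, dict, dict] | None] = {
    "fig2a": (
        "neuron_to_behavior_ablation",
        {"cell": HSN, "cellular_process": GO["cellular_process"],
         "nervous_system_process": POS_REG_EGG, "behavior": GO["egg_laying"]},
        {},
    ),
    "fig2b": None,
    "fig2c": (
        "neuron_to_behavior_activation",
        {"cell": UV1, "cellular_process": GO["depolarization"],
         "nervous_system_process": NEG_REG_EGG, "behavior": GO["egg_laying"]},
        {},
    ),
    "fig3a": (
        "input_neuron_behavior_rescue",
        {"chemical": SEROTONIN, "receptor_activity": "GO:0004993",
         "gene": "WBGene:99000001", "cell": VM, "pathway": "GO:0098664",
         "nervous_system_process": POS_REG_EGG, "behavior": GO["egg_laying"]},
        {},
    ),
    "fig3b": None,
    "fig3c": None,
    "fig4a": (
        "neuron_to_neuron_agnostic",
        {"cell_a": HSN, "cell_b": VC,
         "process_a": GO["depolarization"], "process_b": GO["depolarization"]},
        {("process_a", "process_b"): "RO:0002304"},
    ),
    "fig4b": (
        "neuron_to_neuron_synaptic",
        {"cell_a": VC, "cell_b": HSN,
         "transmission": GO["synaptic_transmission"],
         "process_b": GO["depolarization"]},
        {("transmission", "process_b"): "RO:0002305"},
    ),
    "fig4c": None,
    "fig5": None,
    "fig6c": None,
    "fig6d": None,
}

_FIXTURE_EVIDENCE = {
    "fig2a": _ev("Waggoner1998"),
    "fig2c": _ev("Banerjee2017", ECO_OPTO),
    "fig3a": _ev("Carnell2005"),
    "fig4a": _ev("Collins2016", ECO_OPTO),
    "fig4b": _ev("Kopchock2021", ECO_SYNINHIB),
}


def _fig2b(idx: OntologyIndex) -> CeNCAMModel:
    """Acetylcholine biosynthesis in VC inhibits egg laying: biosynthesis can
    proceed at rest, so it is causally upstream (positive effect) of the
    secretion that is part of the regulating nervous system process."""
    m = CeNCAMModel("fig2b", "acetylcholine biosynthesis in VC regulates egg laying",
                    index=idx)
    ev = _ev("Bany2003")
    biosyn = m.add_individual("GO:0008292")
    vc = m.add_individual(VC)
    secr = m.add_individual("GO:0061526")
    neg = m.add_individual(NEG_REG_EGG)
    beh = m.add_individual(GO["egg_laying"])
    m.assert_edge(biosyn, "BFO:0000066", vc, ev)
    m.assert_edge(biosyn, "RO:0002304", secr, ev)
    m.assert_edge(secr, "BFO:0000050", neg, ev)
    m.assert_edge(neg, "BFO:0000050", beh, ev)
    return m


def _fig3b(idx: OntologyIndex) -> CeNCAMModel:
    """npr-1 rescue of CO2 avoidance in URX, with the implied CO2 receptor
    activity left as a placeholder (no gene, no cell) that joins the circuit
    through the shared nervous system process."""
    m = CeNCAMModel("fig3b", "npr-1 in URX rescues carbon dioxide avoidance",
                    index=idx)
    ev = _ev("Carrillo2013")
    rec = m.add_individual("GO:0170015")      # implied receptor, placeholder
    co2 = m.add_individual(CO2)
    npr1_act = m.add_individual("GO:0004930")
    npr1 = m.add_individual("WBGene:99000002")
    path = m.add_individual("GO:0030522")
    urx = m.add_individual(URX)
    nsp = m.add_individual("GO:0050924")
    beh = m.add_individual(CO2_RESPONSE)
    m.assert_edge(rec, "RO:0012001", co2, ev)
    m.assert_edge(rec, "BFO:0000050", nsp, ev)
    m.assert_edge(npr1_act, "RO:0002333", npr1, ev)
    m.assert_edge(npr1_act, "BFO:0000050", path, ev)
    m.assert_edge(path, "BFO:0000066", urx, ev)
    m.assert_edge(path, "BFO:0000050", nsp, ev)
    m.assert_edge(nsp, "BFO:0000050", beh, ev)
    return m


def _fig3c(idx: OntologyIndex) -> CeNCAMModel:
    """AFD responds to CO2 removal; the receptor is unknown, and the
    'decreasing' temporal feature of the input needs the proposed exposure /
    quality classes (the exposure node is connected only through has
    quality, marking the missing vocabulary)."""
    m = CeNCAMModel("fig3c", "AFD response to carbon dioxide removal", index=idx)
    ev = _ev("Bretscher2011")
    rec = m.add_individual("GO:0038023")      # unknown receptor, no gene/cell
    co2 = m.add_individual(CO2)
    dep = m.add_individual(GO["depolarization"])
    afd = m.add_individual(AFD)
    beh = m.add_individual(CO2_RESPONSE)
    exposure = m.add_individual("CeNCAM:exposure_to_decreasing_carbon_dioxide")
    quality = m.add_individual("CeNCAM:decreasing_amount")
    m.assert_edge(rec, "RO:0002233", co2, ev)
    m.assert_edge(rec, "BFO:0000050", dep, ev)
    m.assert_edge(dep, "BFO:0000066", afd, ev)
    m.assert_edge(dep, "BFO:0000050", beh, ev)
    m.assert_edge(exposure, "RO:0000086", quality, ev)
    return m


def _fig4c(idx: OntologyIndex) -> CeNCAMModel:
    """Subcellular mechanism of the BAG -> RIA connection (simplified):
    vesicular glutamate transport (eat-4) in the synaptic vesicle membrane
    upstream of glr-1 receptor activity driving RIA depolarization."""
    m = CeNCAMModel("fig4c", "vesicle loading mechanism of BAG-to-RIA activation",
                    index=idx)
    ev = _ev("Choi2021")
    transport = m.add_individual("GO:0005313")
    eat4 = m.add_individual("WBGene:99000007")
    vesicle = m.add_individual("GO:0030672")
    trans = m.add_individual(GO["synaptic_transmission"])
    bag = m.add_individual(BAG)
    receptor = m.add_individual("GO:0008066")
    glr1 = m.add_individual("WBGene:99000006")
    dep = m.add_individual(GO["depolarization"])
    ria = m.add_individual(RIA)
    m.assert_edge(transport, "RO:0002333", eat4, ev)
    m.assert_edge(transport, "BFO:0000066", vesicle, ev)
    m.assert_edge(transport, "BFO:0000050", trans, ev)
    m.assert_edge(trans, "BFO:0000066", bag, ev)
    m.assert_edge(transport, "RO:0002304", receptor, ev)
    m.assert_edge(receptor, "RO:0002333", glr1, ev)
    m.assert_edge(receptor, "BFO:0000050", dep, ev)
    m.assert_edge(dep, "BFO:0000066", ria, ev)
    return m


def _fig5(idx: OntologyIndex) -> CeNCAMModel:
    """Compiled egg-laying circuit (AWC, HSN, VC, VM).  Serotonin gets two
    individuals so the HSN->VC connection may be synaptic while HSN->VM is
    extra-synaptic; compiled context licenses the specific *positively/
    negatively regulates* relations."""
    m = CeNCAMModel("fig5", "egg-laying circuit compilation", index=idx)
    p_awc = m.add_individual(GO["cellular_process"])
    awc = m.add_individual(AWC)
    tax4_act = m.add_individual("GO:0038023")
    tax4 = m.add_individual("WBGene:99000003")
    d_hsn = m.add_individual(GO["depolarization"])
    hsn = m.add_individual(HSN)
    biosyn = m.add_individual("GO:0042427")
    tph_act = m.add_individual("GO:0004510")
    tph1 = m.add_individual("WBGene:00006600")
    ser_a = m.add_individual(SEROTONIN)   # synaptic pool (HSN -> VC)
    ser_b = m.add_individual(SEROTONIN)   # extra-synaptic pool (HSN -> VM)
    r_vc = m.add_individual("GO:0099589")
    d_vc = m.add_individual(GO["depolarization"])
    vc = m.add_individual(VC)
    r_vm = m.add_individual("GO:0004993")
    ser1 = m.add_individual("WBGene:99000001")
    path_vm = m.add_individual("GO:0098664")
    vm = m.add_individual(VM)
    pos = m.add_individual(POS_REG_EGG)
    beh = m.add_individual(GO["egg_laying"])

    e_chase = _ev("Chase2004")
    e_collins = _ev("Collins2016", ECO_OPTO)
    e_kop = _ev("Kopchock2021", ECO_SYNINHIB)
    e_carnell = _ev("Carnell2005")
    m.assert_edge(p_awc, "BFO:0000066", awc, e_chase)
    m.assert_edge(tax4_act, "RO:0002333", tax4, e_chase)
    m.assert_edge(tax4_act, "BFO:0000050", p_awc, e_chase)
    m.assert_edge(p_awc, "RO:0002212", d_hsn, e_chase)
    m.assert_edge(d_hsn, "BFO:0000066", hsn, e_collins)
    m.assert_edge(biosyn, "BFO:0000066", hsn, e_carnell)
    m.assert_edge(tph_act, "RO:0002333", tph1, e_carnell)
    m.assert_edge(tph_act, "BFO:0000050", biosyn, e_carnell)
    m.assert_edge(biosyn, "RO:0002234", ser_a, e_carnell)
    m.assert_edge(biosyn, "RO:0002234", ser_b, e_carnell)
    m.assert_edge(r_vc, "RO:0012001", ser_a, e_collins)
    m.assert_edge(r_vc, "BFO:0000050", d_vc, e_collins)
    m.assert_edge(d_vc, "BFO:0000066", vc, e_collins)
    m.assert_edge(d_hsn, "RO:0002213", d_vc, e_collins)
    m.assert_edge(d_vc, "RO:0002212", d_hsn, e_kop)
    m.assert_edge(r_vm, "RO:0002333", ser1, e_carnell)
    m.assert_edge(r_vm, "RO:0012001", ser_b, e_carnell)
    m.assert_edge(r_vm, "BFO:0000050", path_vm, e_carnell)
    m.assert_edge(path_vm, "BFO:0000066", vm, e_carnell)
    m.assert_edge(d_hsn, "RO:0002213", path_vm, e_collins)
    m.assert_edge(path_vm, "BFO:0000050", pos, e_carnell)
    m.assert_edge(pos, "BFO:0000050", beh, e_carnell)
    return m


def _fig6c(idx: OntologyIndex) -> CeNCAMModel:
    """AND logic of CO2 avoidance: the CO2-sensing branch (tax-2 in BAG) and
    the food branch converge via *part of* on one signal-integration
    instance — part of implies necessity, causal edges would not."""
    m = CeNCAMModel("fig6c", "food and CO2 signal integration", index=idx)
    ev = _ev("Bretscher2011")
    rec = m.add_individual("GO:0170015")
    co2 = m.add_individual(CO2)
    sig_co2 = m.add_individual(GO["signal_transduction"])
    tax2_act = m.add_individual("GO:0038023")
    tax2 = m.add_individual("WBGene:99000004")
    bag = m.add_individual(BAG)
    sig_food = m.add_individual(GO["signal_transduction"])
    integ = m.add_individual(SIGNAL_INTEGRATION)
    beh = m.add_individual(CO2_RESPONSE)
    m.assert_edge(rec, "RO:0012001", co2, ev)
    m.assert_edge(rec, "BFO:0000050", sig_co2, ev)
    m.assert_edge(tax2_act, "RO:0002333", tax2, ev)
    m.assert_edge(tax2_act, "BFO:0000050", sig_co2, ev)
    m.assert_edge(sig_co2, "BFO:0000066", bag, ev)
    m.assert_edge(sig_co2, "BFO:0000050", integ, ev)
    m.assert_edge(sig_food, "BFO:0000050", integ, ev)
    m.assert_edge(integ, "BFO:0000050", beh, ev)
    return m


def _fig6d(idx: OntologyIndex) -> CeNCAMModel:
    """Vulval-muscle activation drives egg release only in phase with
    locomotion: both converge on a behavior co-ordination process."""
    m = CeNCAMModel("fig6d", "co-ordination of VM activity with locomotion",
                    index=idx)
    ev = _ev("Kopchock2021", "CeNCAM:mechanical_perturbation_evidence")
    dep = m.add_individual(GO["depolarization"])
    vm = m.add_individual(VM)
    loco = m.add_individual("GO:0007626")
    coord = m.add_individual(BEHAVIOR_COORD)
    beh = m.add_individual(GO["egg_laying"])
    m.assert_edge(dep, "BFO:0000066", vm, ev)
    m.assert_edge(dep, "BFO:0000050", coord, ev)
    m.assert_edge(loco, "BFO:0000050", coord, ev)
    m.assert_edge(coord, "BFO:0000050", beh, ev)
    return m


_DIRECT_BUILDERS = {
    "fig2b": _fig2b, "fig3b": _fig3b, "fig3c": _fig3c, "fig4c": _fig4c,
    "fig5": _fig5, "fig6c": _fig6c, "fig6d": _fig6d,
}


def worked_example(name: str, index: OntologyIndex | None = None) -> CeNCAMModel:
    """Build one of the twelve worked-example models by name."""
    if name not in FIXTURE_MODEL_NAMES:
        raise CencamError(f"unknown fixture model {name!r}")
    idx = index if index is not None else builtin_ontology()
    assigned = ASSIGNED_TEMPLATES.get(name)
    if assigned is not None:
        tname, bindings, overrides = assigned
        return _templates.instantiate(
            _templates.get_template(tname), bindings, overrides, index=idx,
            evidence=_FIXTURE_EVIDENCE[name], model_id=name)
    return _DIRECT_BUILDERS[name](idx)


def all_worked_examples(index: OntologyIndex | None = None) -> dict[str, CeNCAMModel]:
    return {name: worked_example(name, index) for name in FIXTURE_MODEL_NAMES}


# ---------------------------------------------------------------------------
# Connectome overlay fixtures
# ---------------------------------------------------------------------------


def fixture_connectome():
    """The shipped mini-connectome (hand-derived, synthetic edge list)."""
    from .connectome import load_connectome

    text = (resources.files("cencam") / "data" / "fig8_connectome.tsv").read_text()
    return load_connectome(text)


def overlay_models(index: OntologyIndex | None = None) -> list[CeNCAMModel]:
    """Per-neuron functional models behind the annotated-connectome example:
    CO2 responses (BAG +, ASH +, AFD -), egg-laying effects (HSN +, VM +,
    VC -, uv1 -, AWC -), CO2-avoidance effects (BAG +, AFD +), serotonin
    responses (VC +, VM +), and the signed VC->HSN / HSN->VC connections."""
    idx = index if index is not None else builtin_ontology()
    models: list[CeNCAMModel] = []

    def behavior_model(mid, neuron, proc_cls, rel, behavior_cls, ref):
        m = CeNCAMModel(mid, index=idx)
        ev = _ev(ref)
        p = m.add_individual(proc_cls)
        n = m.add_individual(neuron)
        b = m.add_individual(behavior_cls)
        m.assert_edge(p, "BFO:0000066", n, ev)
        m.assert_edge(p, rel, b, ev)
        return m

    models.append(behavior_model("fig8-hsn", HSN, GO["depolarization"],
                                 "RO:0002213", GO["egg_laying"], "Waggoner1998"))
    models.append(behavior_model("fig8-vc", VC, GO["depolarization"],
                                 "RO:0002212", GO["egg_laying"], "Bany2003"))
    models.append(behavior_model("fig8-uv1", UV1, GO["depolarization"],
                                 "RO:0002212", GO["egg_laying"], "Banerjee2017"))
    models.append(behavior_model("fig8-vm", VM, GO["depolarization"],
                                 "RO:0002213", GO["egg_laying"], "Kopchock2021"))
    models.append(behavior_model("fig8-awc", AWC, GO["cellular_process"],
                                 "RO:0002212", GO["egg_laying"], "FentonRise2016"))

    def response_model(mid, neuron, chem, effect_rel, ref,
                       behavior_cls=None, behavior_rel=None):
        m = CeNCAMModel(mid, index=idx)
        ev = _ev(ref)
        rec = m.add_individual("GO:0038023")
        c = m.add_individual(chem)
        resp = m.add_individual("GO:0010037" if chem == CO2 else GO["cellular_process"])
        dep = m.add_individual(GO["depolarization"])
        n = m.add_individual(neuron)
        m.assert_edge(rec, "RO:0012001", c, ev)
        m.assert_edge(rec, "BFO:0000050", resp, ev)
        m.assert_edge(resp, effect_rel, dep, ev)
        m.assert_edge(dep, "BFO:0000066", n, ev)
        if behavior_cls is not None:
            b = m.add_individual(behavior_cls)
            m.assert_edge(dep, behavior_rel, b, ev)
        return m

    models.append(response_model("fig8-bag-co2", BAG, CO2, "RO:0002304",
                                 "Hallem2008", CO2_AVOIDANCE, "RO:0002213"))
    models.append(response_model("fig8-ash-co2", ASH, CO2, "RO:0002304",
                                 "Fenk2015"))
    models.append(response_model("fig8-afd-co2", AFD, CO2, "RO:0002305",
                                 "Bretscher2011", CO2_AVOIDANCE, "RO:0002213"))
    models.append(response_model("fig8-vc-ser", VC, SEROTONIN, "RO:0002304",
                                 "Shyn2003"))
    models.append(response_model("fig8-vm-ser", VM, SEROTONIN, "RO:0002304",
                                 "Shyn2003"))

    # signed neuron-to-neuron connections
    m = CeNCAMModel("fig8-vc-hsn", index=idx)
    ev = _ev("Kopchock2021", ECO_SYNINHIB)
    trans = m.add_individual(GO["synaptic_transmission"])
    vc = m.add_individual(VC)
    dep = m.add_individual(GO["depolarization"])
    hsn = m.add_individual(HSN)
    m.assert_edge(trans, "BFO:0000066", vc, ev)
    m.assert_edge(trans, "RO:0002305", dep, ev)
    m.assert_edge(dep, "BFO:0000066", hsn, ev)
    models.append(m)

    m = CeNCAMModel("fig8-hsn-vc", index=idx)
    ev = _ev("Collins2016", ECO_OPTO)
    d1 = m.add_individual(GO["depolarization"])
    hsn = m.add_individual(HSN)
    d2 = m.add_individual(GO["depolarization"])
    vc = m.add_individual(VC)
    m.assert_edge(d1, "BFO:0000066", hsn, ev)
    m.assert_edge(d1, "RO:0002304", d2, ev)
    m.assert_edge(d2, "BFO:0000066", vc, ev)
    models.append(m)
    return models


def sample_statement_records() -> list[StatementRecord]:
    """The shipped sample statement table."""
    text = (resources.files("cencam") / "data" / "sample_statements.tsv").read_text()
    return read_statement_table(text)


# ---------------------------------------------------------------------------
# Seeded random generators
# ---------------------------------------------------------------------------

# (rule key, subject aspect pool, relation choices, object aspect pool)
_VALID_ROWS = [
    ("causal_mf", "molecular_function",
     ("RO:0002418", "RO:0002411", "RO:0002304", "RO:0002305", "RO:0002213",
      "RO:0002212"), "molecular_function"),
    ("causal_bp", "biological_process",
     ("RO:0002418", "RO:0002411", "RO:0002304", "RO:0002305", "RO:0002213",
      "RO:0002212"), "biological_process"),
    ("partof_mf", "molecular_function", ("BFO:0000050",), "biological_process"),
    ("partof_bp", "biological_process", ("BFO:0000050",), "biological_process"),
    ("enabled_by", "molecular_function", ("RO:0002333",), "gene"),
    ("occurs_in_anat", "biological_process", ("BFO:0000066",), "anatomy"),
    ("occurs_in_cc", "molecular_function", ("BFO:0000066",), "cellular_component"),
    ("small_mol", "molecular_function", ("RO:0012001",), "chemical"),
    ("has_input", "molecular_function", ("RO:0002233",), "chemical"),
    ("has_output", "biological_process", ("RO:0002234",), "chemical"),
    ("has_quality", "exposure", ("RO:0000086",), "quality"),
]

# deliberate single-error breakages of named rules
_INVALID_ROWS = [
    ("BAD_ENABLED_BY", "gene", ("RO:0002333",), "molecular_function"),
    ("BAD_PARTOF", "biological_process", ("BFO:0000050",), "molecular_function"),
    ("BAD_PARTOF", "anatomy", ("BFO:0000050",), "biological_process"),
    ("BAD_OCCURS_IN", "biological_process", ("BFO:0000066",), "chemical"),
    ("BAD_OCCURS_IN", "anatomy", ("BFO:0000066",), "anatomy"),
    ("BAD_CAUSAL_DOMAIN", "biological_process", ("RO:0002304",), "anatomy"),
    ("BAD_CAUSAL_DOMAIN", "chemical", ("RO:0002213",), "biological_process"),
    ("BAD_SMALL_MOL", "biological_process", ("RO:0012001",), "chemical"),
    ("BAD_INPUT_OUTPUT", "molecular_function", ("RO:0002233",), "anatomy"),
    ("BAD_QUALITY", "biological_process", ("RO:0000086",), "quality"),
]


def _aspect_pools(idx: OntologyIndex) -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {}
    for c in sorted(idx.terms):
        pools.setdefault(idx.aspect(c), []).append(c)
    return pools


def random_model(seed: int, n_nodes: int = 20, n_edges: int = 30,
                 p_invalid: float = 0.0,
                 index: OntologyIndex | None = None
                 ) -> tuple[CeNCAMModel, int]:
    """Seeded random model with a known number of planted rule violations.

    Each edge is drawn from a valid rule row, or — with probability
    *p_invalid* — from a deliberate breakage producing exactly one validator
    error.  Returns the model and the planted error count.  Pure function of
    the seed: the same seed yields an identical serialization.
    """
    idx = index if index is not None else builtin_ontology()
    rng = random.Random(seed)
    pools = _aspect_pools(idx)
    m = CeNCAMModel(f"random-{seed}", index=idx)
    ev = _ev("random")
    aspects = sorted(pools)
    ids_by_aspect: dict[str, list[str]] = {a: [] for a in aspects}
    for _ in range(n_nodes):
        aspect = rng.choice(aspects)
        cls = rng.choice(pools[aspect])
        ids_by_aspect[aspect].append(m.add_individual(cls))
    planted = 0
    for _ in range(n_edges):
        invalid = rng.random() < p_invalid
        rows = _INVALID_ROWS if invalid else _VALID_ROWS
        for _attempt in range(30):
            key, sa, rels, oa = rng.choice(rows)
            subjects = ids_by_aspect.get(sa, [])
            objects = ids_by_aspect.get(oa, [])
            if not subjects or not objects:
                continue
            s = rng.choice(subjects)
            o = rng.choice(objects)
            rel = rng.choice(rels)
            if s == o or (s, rel, o) in m._triples:
                continue
            m.assert_edge(s, rel, o, ev)
            if invalid:
                planted += 1
            break
    return m, planted


_CHAIN_SHAPES = [
    (GO["depolarization"], "BFO:0000066", UV1, "BFO:0000050", NEG_REG_EGG,
     "BFO:0000050", GO["egg_laying"]),
    (GO["cellular_process"], "BFO:0000066", HSN, "RO:0002418", POS_REG_EGG,
     "BFO:0000050", GO["egg_laying"]),
    (GO["synaptic_transmission"], "BFO:0000066", VC, "RO:0002305",
     GO["depolarization"], "BFO:0000066", HSN),
    (GO["signal_transduction"], "BFO:0000066", BAG, "BFO:0000050",
     SIGNAL_INTEGRATION, "BFO:0000050", CO2_RESPONSE),
    (GO["depolarization"], "BFO:0000066", VM, "BFO:0000050", BEHAVIOR_COORD,
     "BFO:0000050", GO["egg_laying"]),
]

_WORDS = ("ablation", "rescue", "optogenetic", "activation", "inhibition",
          "calcium", "imaging", "mutant", "behavior", "circuit", "neuron",
          "egg-laying", "avoidance", "response", "synaptic", "peptidergic")


def random_statement_table(seed: int, n_statements: int, n_papers: int
                           ) -> tuple[str, CurationStats]:
    """Seeded random statement table plus its planted curation statistics.

    Statements may repeat as multiple entries (rows); references cycle over
    *n_papers* citation keys.  Byte-identical output for the same seed.
    """
    rng = random.Random(seed)
    records: list[StatementRecord] = []
    for i in range(n_statements):
        local_id = f"EL{i + 1:02d}"
        ref = f"Paper{(i % n_papers) + 1}" if n_papers else "Paper1"
        entries = 1 + (1 if rng.random() < 0.3 else 0)
        for _ in range(entries):
            cells = rng.choice(_CHAIN_SHAPES)
            text = " ".join(rng.choice(_WORDS) for _ in range(8))
            chain = tuple((cells[j], cells[j + 1], cells[j + 2])
                          for j in range(0, len(cells) - 2, 2))
            records.append(StatementRecord(local_id, ref, text, chain))
    return write_statement_table(records), statement_stats(records)
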