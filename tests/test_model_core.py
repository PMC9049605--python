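"""Model container, I/O, enzyme-constraint detection and strain edits."""

import math

import pytest

from ecdyn.lp import solve_lp
from ecdyn.model import (EcInfo, FormatError, MetabolicModel, Metabolite,
                         ModelEdit, Reaction, ValidationError, add_reaction,
                         apply_edit, apply_knockout, detect_ec_structure,
                         load_model, rescale_pool_coefficients,
                         rescale_small_coefficients, resolve_uptake,
                         restrict_secretions, save_model, scale_protein_pool,
                         set_flux_bounds)
from ecdyn.toys import OverflowToySpec, overflow_toy, plain_twin


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

def test_undeclared_metabolite_rejected():
    mets = [Metabolite("a")]
    with pytest.raises(ValidationError, match="undeclared metabolite"):
        MetabolicModel(mets, [Reaction("r1", {"a": -1, "ghost": 1})])


def test_duplicate_ids_rejected():
    mets = [Metabolite("a")]
    with pytest.raises(ValidationError, match="duplicate"):
        MetabolicModel(mets, [Reaction("r", {"a": -1}),
                              Reaction("r", {"a": 1})])
    with pytest.raises(ValidationError, match="duplicate"):
        MetabolicModel([Metabolite("a"), Metabolite("a")], [])


def test_inverted_bounds_rejected():
    with pytest.raises(ValidationError):
        Reaction("r", {"a": 1}, lower_bound=1.0, upper_bound=0.0)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_json_round_trip_exact(toy_model, tmp_path):
    path = tmp_path / "toy.json"
    save_model(toy_model, path, "json")
    back = load_model(path, "json")
    assert set(back.reactions) == set(toy_model.reactions)
    assert len(back.reactions) == 8
    assert len(back.metabolites) == 6
    for rid, r in toy_model.reactions.items():
        b = back.reactions[rid]
        assert b.stoich == r.stoich
        assert (b.lower_bound, b.upper_bound) == (r.lower_bound, r.upper_bound)
    assert back.ec is not None
    assert back.ec.pool_coefficient == toy_model.ec.pool_coefficient


def test_sbml_export_matches_json(toy_model, tmp_path):
    jpath, xpath = tmp_path / "toy.json", tmp_path / "toy.xml"
    save_model(toy_model, jpath, "json")
    save_model(toy_model, xpath, "sbml")
    a, b = load_model(jpath), load_model(xpath)
    assert set(a.reactions) == set(b.reactions)
    for rid in a.reactions:
        assert a.reactions[rid].stoich == b.reactions[rid].stoich
        assert a.reactions[rid].lower_bound == b.reactions[rid].lower_bound
        assert a.reactions[rid].upper_bound == b.reactions[rid].upper_bound
    assert b.objective_reaction_id == "R_grow"


def test_load_invalid_reference_fails(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"metabolites": [{"id": "a"}], '
                    '"reactions": [{"id": "r", "stoich": {"ghost": 1}, '
                    '"lb": 0, "ub": 1}]}')
    with pytest.raises(ValidationError, match="ghost"):
        load_model(path, "json")


def test_load_garbage_is_format_error(tmp_path):
    path = tmp_path / "junk.json"
    path.write_text("not json {")
    with pytest.raises(FormatError):
        load_model(path, "json")


# ---------------------------------------------------------------------------
# enzyme-constraint detection
# ---------------------------------------------------------------------------

def test_detect_direct_pool(toy_model):
    ec = detect_ec_structure(toy_model)
    assert ec is not None
    assert ec.pool_exchange_id == "prot_pool_exchange"
    assert ec.pool_coefficient == pytest.approx(
        {"R_resp": 0.010, "R_ferm": 0.002})
    assert ec.mode == "direct"


def test_detect_plain_gem_returns_none(toy_model):
    assert detect_ec_structure(plain_twin(toy_model)) is None


def _draw_chain_model():
    """GECKO-style encoding: pool -> enzyme pseudo-metabolites (MW) ->
    catalysed reactions (1/kcat)."""
    mets = [Metabolite("s"), Metabolite("x"), Metabolite("prot_pool"),
            Metabolite("prot_E1"), Metabolite("prot_E2")]
    rxns = [
        Reaction("EX_S", {"s": 1.0}, 0, 10),
        Reaction("prot_pool_exchange", {"prot_pool": 1.0}, 0, 0.02),
        # MW 50000 g/mol expressed per mmol: 50 g/mmol
        Reaction("draw_prot_E1", {"prot_pool": -50.0, "prot_E1": 1.0}, 0, 1000),
        Reaction("draw_prot_E2", {"prot_pool": -20.0, "prot_E2": 1.0}, 0, 1000),
        # kcat 5000/h -> coefficient 1/5000
        Reaction("R_cat", {"s": -1.0, "x": 0.1,
                           "prot_E1": -1 / 5000, "prot_E2": -1 / 10000},
                 0, 1000),
        Reaction("R_grow", {"x": -1.0}, 0, 1000),
    ]
    return MetabolicModel(mets, rxns, objective_reaction_id="R_grow")


def test_detect_draw_chain_aggregates_mw_over_kcat():
    ec = detect_ec_structure(_draw_chain_model())
    assert ec is not None
    assert ec.mode == "draw_chain"
    assert ec.enzyme_metabolite_ids == {"prot_E1", "prot_E2"}
    # net pool cost = 50/5000 + 20/10000
    assert ec.pool_coefficient["R_cat"] == pytest.approx(0.012)


def test_detect_ambiguous_pool_needs_hint():
    mets = [Metabolite("pool_a"), Metabolite("pool_b"), Metabolite("s"),
            Metabolite("x")]
    rxns = [Reaction("EX_pool_a", {"pool_a": 1.0}, 0, 1),
            Reaction("EX_pool_b", {"pool_b": 1.0}, 0, 1),
            Reaction("EX_S", {"s": 1.0}, 0, 10),
            Reaction("R1", {"s": -1, "pool_a": -0.1, "x": 1}, 0, 10),
            Reaction("R2", {"s": -1, "pool_b": -0.1, "x": 1}, 0, 10),
            Reaction("R_grow", {"x": -1}, 0, 1000)]
    m = MetabolicModel(mets, rxns)
    with pytest.raises(ValidationError, match="ambiguous"):
        detect_ec_structure(m)
    ec = detect_ec_structure(m, pool_id_hint="EX_pool_a")
    assert ec.pool_exchange_id == "EX_pool_a"


# ---------------------------------------------------------------------------
# uptake accessor (convention-blind)
# ---------------------------------------------------------------------------

def test_resolve_uptake_conventions():
    # irreversible ec convention: _REV exchange imports with positive flux
    mets = [Metabolite("g")]
    m_ec = MetabolicModel(mets, [Reaction("EX_g", {"g": -1.0}, 0, 1000),
                                 Reaction("EX_g_REV", {"g": 1.0}, 0, 10)])
    assert resolve_uptake(m_ec, "EX_g") == ("EX_g_REV", 1)
    # signed plain-GEM convention: uptake is the negative direction
    m_plain = MetabolicModel(mets, [Reaction("EX_g", {"g": -1.0}, -10, 1000)])
    assert resolve_uptake(m_plain, "EX_g") == ("EX_g", -1)
    # toy convention: forward exchange produces the metabolite
    m_toy = MetabolicModel(mets, [Reaction("EX_g", {"g": 1.0}, 0, 10)])
    assert resolve_uptake(m_toy, "EX_g") == ("EX_g", 1)
    with pytest.raises(KeyError):
        resolve_uptake(m_toy, "EX_missing")


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------

def test_set_flux_bounds_is_local(toy_model):
    m2 = set_flux_bounds(toy_model, "R_grow", 0.1, 0.1)
    assert (m2.reactions["R_grow"].lower_bound,
            m2.reactions["R_grow"].upper_bound) == (0.1, 0.1)
    for rid in toy_model.reactions:
        if rid == "R_grow":
            continue
        a, b = toy_model.reactions[rid], m2.reactions[rid]
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
    # original untouched
    assert toy_model.reactions["R_grow"].upper_bound == 1000.0


def test_set_flux_bounds_errors(toy_model):
    with pytest.raises(KeyError):
        set_flux_bounds(toy_model, "nope", 0, 0)
    with pytest.raises(ValidationError):
        set_flux_bounds(toy_model, "EX_S", 1.0, 0.0)


def test_blocked_uptake_stops_growth(toy_model):
    m2 = set_flux_bounds(toy_model, "EX_S", 0.0, 0.0)
    assert solve_lp(m2, "R_grow", "max").objective_value == pytest.approx(0.0)


def test_knockout_matches_isozymes_and_rev_twins():
    mets = [Metabolite("s"), Metabolite("x")]
    rxns = [Reaction("EX_S", {"s": 1.0}, 0, 10),
            Reaction("r_0959No1", {"s": -1, "x": 0.1}, 0, 10),
            Reaction("r_0959No2", {"s": -1, "x": 0.1}, 0, 10),
            Reaction("r_0959_REVNo1", {"s": 1, "x": -0.1}, 0, 10),
            Reaction("r_09599", {"s": -1, "x": 0.2}, 0, 10),  # not a match
            Reaction("R_grow", {"x": -1}, 0, 1000)]
    m = MetabolicModel(mets, rxns)
    m2 = apply_knockout(m, ["r_0959"])
    for rid in ("r_0959No1", "r_0959No2", "r_0959_REVNo1"):
        assert m2.reactions[rid].upper_bound == 0.0
    assert m2.reactions["r_09599"].upper_bound == 10.0


def test_knockout_of_fermentation_removes_ethanol(toy_model):
    m2 = apply_knockout(toy_model, ["R_ferm"])
    m2 = set_flux_bounds(m2, "R_grow", 0.15, 0.15)
    sol = solve_lp(m2, "EX_S", "min")
    assert sol.ok
    assert sol.fluxes["EX_etoh"] == pytest.approx(0.0, abs=1e-9)


def test_knockout_growth_reaction_zeroes_mu(toy_model):
    m2 = apply_knockout(toy_model, ["R_grow"])
    assert solve_lp(m2, "R_grow", "max").objective_value == pytest.approx(0.0)


def test_empty_knockout_is_identity(toy_model):
    m2 = apply_knockout(toy_model, [])
    for rid, r in toy_model.reactions.items():
        assert (r.lower_bound, r.upper_bound) == \
            (m2.reactions[rid].lower_bound, m2.reactions[rid].upper_bound)


def test_add_heterologous_reaction_enables_secretion(toy_model):
    """Lactate-dehydrogenase-style addition: new route + new exchange."""
    m2 = add_reaction(toy_model,
                      Reaction("R_ldh", {"s": -1.0, "lac": 2.0, "x": 0.02},
                               0, 1000),
                      pool_coefficient=0.003,
                      new_metabolites=(Metabolite("lac", "lactate"),))
    m2 = add_reaction(m2, Reaction("EX_lac", {"lac": -1.0}, 0, 1000))
    m2 = set_flux_bounds(m2, "R_grow", 0.05, 0.05)
    sol = solve_lp(m2, "EX_lac", "max")
    assert sol.ok and sol.objective_value > 1.0
    assert m2.ec.pool_coefficient["R_ldh"] == 0.003


def test_add_reaction_errors(toy_model):
    with pytest.raises(ValidationError, match="already in model"):
        add_reaction(toy_model, Reaction("R_grow", {"x": -1}, 0, 1))
    with pytest.raises(ValidationError, match="empty stoichiometry"):
        add_reaction(toy_model, Reaction("R_empty", {}, 0, 1))
    plain = plain_twin(toy_model)
    with pytest.raises(ValidationError, match="without"):
        add_reaction(plain, Reaction("R_new", {"s": -1}, 0, 1),
                     pool_coefficient=0.01)


def test_scale_protein_pool(toy_model, toy_analytic):
    m2 = scale_protein_pool(toy_model, 2.0)
    assert m2.ec.pool_upper_bound == pytest.approx(0.04)
    # critical growth doubles: respiration-only feasible up to pool*y_r/c_r
    m2 = set_flux_bounds(m2, "R_grow", 2 * toy_analytic.mu_crit,
                         2 * toy_analytic.mu_crit)
    sol = solve_lp(m2, "EX_S", "min")
    assert sol.fluxes["R_ferm"] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValidationError):
        scale_protein_pool(toy_model, 0.0)
    with pytest.raises(ValidationError):
        scale_protein_pool(plain_twin(toy_model), 1.25)


def test_scale_pool_identity(toy_model):
    m2 = scale_protein_pool(toy_model, 1.0)
    assert m2.ec.pool_upper_bound == toy_model.ec.pool_upper_bound


def test_restrict_secretions(toy_model):
    m2 = restrict_secretions(toy_model, [])
    # ethanol secretion closed, gases kept, uptake untouched
    assert m2.reactions["EX_etoh"].upper_bound == 0.0
    assert m2.reactions["EX_co2"].upper_bound == 1000.0
    assert m2.reactions["EX_S"].upper_bound == 10.0
    m3 = restrict_secretions(toy_model, ["EX_etoh"])
    for rid, r in toy_model.reactions.items():
        assert (r.lower_bound, r.upper_bound) == \
            (m3.reactions[rid].lower_bound, m3.reactions[rid].upper_bound)
    with pytest.raises(ValidationError, match="not an exchange"):
        restrict_secretions(toy_model, ["R_resp"])


def test_rescale_small_coefficients_preserves_optimum():
    spec = OverflowToySpec()
    m, _ = overflow_toy(spec)
    true_opt = solve_lp(m, "R_grow", "max").objective_value
    # shrink the pool unit by 1e9 (as if coefficients were in g and tiny);
    # the raw LP now loses the pool constraint to solver tolerances
    for rid in ("R_resp", "R_ferm"):
        m.reactions[rid].stoich["prot_pool"] *= 1e-9
    m.reactions["prot_pool_exchange"].upper_bound *= 1e-9
    corrupted = solve_lp(m, "R_grow", "max").objective_value
    assert corrupted > true_opt + 0.1  # the instability the rescale fixes
    m2, report = rescale_small_coefficients(m, 1e-7)
    assert report  # pool exchange rescaled
    assert all(abs(c) >= 1e-7 for r in m2.reactions.values()
               for c in r.stoich.values() if c != 0)
    new = solve_lp(m2, "R_grow", "max").objective_value
    assert new == pytest.approx(true_opt, rel=1e-6)


def test_rescale_identity_and_errors(toy_model):
    m2, report = rescale_small_coefficients(toy_model, 1e-7)
    assert report == {}
    with pytest.raises(ValidationError):
        rescale_small_coefficients(toy_model, 0.0)


def test_rescale_cap_breach_names_metabolite():
    mets = [Metabolite("m"), Metabolite("s")]
    rxns = [Reaction("R1", {"s": -1, "m": 1e-12}, 0, 10),
            Reaction("R2", {"s": 1, "m": -1e6}, 0, 10)]
    m = MetabolicModel(mets, rxns)
    with pytest.raises(ValidationError, match="'m'"):
        rescale_small_coefficients(m, 1e-6, coefficient_cap=1e8)


def test_rescale_kcat_hook(toy_model):
    m2 = rescale_pool_coefficients(toy_model, {"R_resp": 2.0})
    assert m2.ec.pool_coefficient["R_resp"] == pytest.approx(0.02)
    assert m2.reactions["R_resp"].stoich["prot_pool"] == pytest.approx(-0.02)
    assert m2.ec.pool_coefficient["R_ferm"] == pytest.approx(0.002)


def test_declarative_edits(toy_model):
    edit = ModelEdit("scale_pool", {"factor": 1.25})
    m2 = apply_edit(toy_model, edit)
    assert m2.ec.pool_upper_bound == pytest.approx(0.025)
    with pytest.raises(ValidationError, match="unknown edit kind"):
        ModelEdit("frobnicate", {})
    with pytest.raises(ValidationError, match="missing payload"):
        ModelEdit("set_bounds", {"reaction_id": "R_grow"})


def test_ecinfo_invariants():
    with pytest.raises(ValidationError):
        EcInfo("ex", "pool", 0.0)
    with pytest.raises(ValidationError):
        EcInfo("ex", "pool", 0.02, pool_coefficient={"r": -1.0})
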