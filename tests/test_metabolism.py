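import numpy as np
import pytest

from ebaflux._gpr import parse_gpr
from ebaflux.io import MetabolicModelFile, Reaction
from ebaflux.metabolism import (FluxBounds, TrameParams, essentiality,
                                expression_ratios, fba, fva,
                                reaction_activity, trame_bounds)


def _cobra_optimum(model, bounds):
    """Independent LP oracle: the same problem solved by cobra/GLPK."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("oracle")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    for r in model.reactions:
        lo, hi = bounds[r.id]
        rxn = cobra.Reaction(r.id, lower_bound=lo, upper_bound=hi)
        cm.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
    cm.objective = model.biomass_reaction_id
    sol = cm.optimize()
    return None if sol.status != "optimal" else float(sol.objective_value)


# ---------------------------------------------------------------------------
# FBA


def test_chain_growth_forced_to_uptake(chain_model):
    state = fba(chain_model)
    assert state.status == "optimal"
    assert state.growth == pytest.approx(10.0, abs=1e-9)
    # mass balance
    S = chain_model.stoichiometric_matrix()
    v = np.array([state.v[r.id] for r in chain_model.reactions])
    assert np.abs(S @ v).max() < 1e-6


def test_closed_reaction_kills_growth(chain_model):
    bounds = FluxBounds.from_model(chain_model).with_overrides(
        [("R1", 0.0, 0.0)])
    state = fba(chain_model, bounds)
    assert state.growth == pytest.approx(0.0, abs=1e-9)


def test_diamond_split(diamond_model):
    state = fba(diamond_model)
    assert state.growth == pytest.approx(10.0, abs=1e-9)
    assert state.v["R2"] + state.v["R3"] == pytest.approx(10.0, abs=1e-6)
    assert state.growth == pytest.approx(
        _cobra_optimum(diamond_model, FluxBounds.from_model(diamond_model)),
        abs=1e-6)


def test_unknown_objective(chain_model):
    with pytest.raises(KeyError):
        fba(chain_model, objective="NOPE")


def _random_toy_model(seed):
    """Feasible random model: a chain plus random shortcut reactions."""
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(3, 7))
    mets = [f"M{i}" for i in range(n_mets)]
    reactions = [Reaction("EX_in", {"M0": 1.0}, 0.0, float(rng.integers(5, 15)),
                          is_exchange=True)]
    for i in range(1, n_mets):
        reactions.append(Reaction(f"C{i}", {mets[i - 1]: -1.0, mets[i]: 1.0},
                                  0.0, float(rng.integers(5, 25))))
    n_extra = int(rng.integers(1, 6))
    for k in range(n_extra):
        a, b = rng.choice(n_mets, size=2, replace=False)
        lb = float(rng.choice([0.0, -10.0]))
        reactions.append(Reaction(f"X{k}", {mets[a]: -1.0, mets[b]: 1.0},
                                  lb, float(rng.integers(1, 20))))
    reactions.append(Reaction("BIO", {mets[-1]: -1.0}, 0.0, 1000.0))
    return MetabolicModelFile(mets, reactions, "BIO")


@pytest.mark.parametrize("seed", range(20))
def test_fba_matches_cobra_oracle_random_models(seed):
    model = _random_toy_model(seed)
    bounds = FluxBounds.from_model(model)
    mine = fba(model, bounds)
    oracle = _cobra_optimum(model, bounds)
    if oracle is None:
        assert mine.status == "infeasible"
    else:
        assert mine.growth == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize("seed", range(20))
def test_fva_sandwich_random_models(seed):
    model = _random_toy_model(seed)
    frac = 0.5
    state = fba(model)
    ranges = fva(model, biomass_fraction=frac)
    # re-solve FBA restricted to the same biomass fraction: its vertex must
    # lie inside every FVA interval
    for r in model.reactions:
        lo, hi = ranges[r.id]
        assert lo <= hi + 1e-9
    ranges_full = fva(model, biomass_fraction=0.0)
    for r in model.reactions:
        lo, hi = ranges_full[r.id]
        assert lo - 1e-6 <= state.v[r.id] <= hi + 1e-6


# ---------------------------------------------------------------------------
# FVA


def test_fva_diamond_alternative_route(diamond_model):
    ranges = fva(diamond_model, biomass_fraction=1.0)
    assert ranges["R2"] == (pytest.approx(0.0, abs=1e-7),
                            pytest.approx(10.0, abs=1e-7))


def test_fva_chain_collapses_to_point(chain_model):
    ranges = fva(chain_model, biomass_fraction=1.0)
    for rid in ("EX_A", "R1", "BIO"):
        lo, hi = ranges[rid]
        assert hi - lo < 1e-6
        assert lo == pytest.approx(10.0, abs=1e-6)


def test_fva_blocked_reaction_is_zero():
    model = MetabolicModelFile(
        ["A", "B", "X", "Y"],
        [
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIO", {"B": -1.0}, 0.0, 1000.0),
            Reaction("ORPHAN", {"X": -1.0, "Y": 1.0}, 0.0, 1000.0),
        ],
        "BIO",
    )
    ranges = fva(model, biomass_fraction=0.0)
    assert ranges["ORPHAN"] == (pytest.approx(0.0, abs=1e-9),
                                pytest.approx(0.0, abs=1e-9))


def test_fva_fraction_domain(chain_model):
    with pytest.raises(ValueError):
        fva(chain_model, biomass_fraction=1.5)


# ---------------------------------------------------------------------------
# GPR activity & TRAME


def test_activity_and_min():
    assert reaction_activity(parse_gpr("g1 and g2"),
                             {"g1": 0.5, "g2": 1.0}) == 0.5


def test_activity_or_max():
    assert reaction_activity(parse_gpr("g1 or g2"),
                             {"g1": 0.5, "g2": 1.0}) == 1.0


def test_activity_nested():
    tree = parse_gpr("(g1 and g2) or g3")
    assert reaction_activity(tree, {"g1": 0.2, "g2": 0.8, "g3": 0.1}) \
        == pytest.approx(0.2)


def test_activity_no_gpr_is_one():
    assert reaction_activity(None, {}) == 1.0


def _single_enzyme_setup(fitted_model, chain_model):
    envelope = fva(chain_model, biomass_fraction=0.0)
    return envelope


def test_trame_identity_at_wild_type(fitted_model, chain_model):
    envelope = fva(chain_model)
    out = trame_bounds(envelope, chain_model, fitted_model.y_wt, fitted_model)
    assert out.bounds == envelope.bounds


def test_trame_halves_bound_on_minus_one_log2(fitted_model, chain_model):
    m = fitted_model
    # chain_model's R1 is gated by gene "gE", unknown to the fitted model,
    # so pass ratios via a model-aligned vector on a renamed GPR instead
    g = m.genes[15]
    chain = chain_model
    chain.reactions[1].gpr = parse_gpr(g)
    envelope = fva(chain)
    y = m.y_wt.copy()
    y[m.index(g)] -= max(1.0, 3 * m.sigma_wt[m.index(g)] + 1.0)
    shift = y[m.index(g)] - m.y_wt[m.index(g)]
    out = trame_bounds(envelope, chain, y, m)
    lo, hi = out["R1"]
    assert hi == pytest.approx(envelope["R1"][1] * 2.0 ** shift, rel=1e-9)
    assert lo == envelope["R1"][0]


def test_trame_cap(fitted_model, chain_model):
    m = fitted_model
    g = m.genes[15]
    chain_model.reactions[1].gpr = parse_gpr(g)
    envelope = FluxBounds({"EX_A": (0.0, 10.0), "R1": (0.0, 3.0),
                           "BIO": (0.0, 10.0)})
    y = m.y_wt.copy()
    y[m.index(g)] += 10.0  # +10 log2, far past any gate
    out = trame_bounds(envelope, chain_model, y, m,
                       TrameParams(n=2.0, p_cap=10.0))
    assert out["R1"][1] == pytest.approx(30.0)


def test_trame_gate_inside_n_sigma(fitted_model, chain_model):
    m = fitted_model.copy()
    g = m.genes[15]
    i = m.index(g)
    m.sigma_wt[i] = 1.0
    chain_model.reactions[1].gpr = parse_gpr(g)
    envelope = fva(chain_model)
    y = m.y_wt.copy()
    y[i] += 1.5  # inside the 2-sigma gate
    out = trame_bounds(envelope, chain_model, y, m, TrameParams(n=2.0))
    assert out.bounds == envelope.bounds


def test_trame_identity_as_n_goes_to_infinity(fitted_model, chain_model):
    m = fitted_model
    g = m.genes[15]
    chain_model.reactions[1].gpr = parse_gpr(g)
    envelope = fva(chain_model)
    rng = np.random.default_rng(0)
    y = m.y_wt + rng.normal(0, 2.0, m.n_genes)
    out = trame_bounds(envelope, chain_model, y, m, TrameParams(n=np.inf))
    assert out.bounds == envelope.bounds
    # and for positive sigma a large finite n suffices
    m2 = m.copy()
    m2.sigma_wt = np.full(m.n_genes, 0.5)
    out2 = trame_bounds(envelope, chain_model, y, m2, TrameParams(n=1e9))
    assert out2.bounds == envelope.bounds


def test_trame_monotone_in_rho(fitted_model, chain_model):
    m = fitted_model
    g = m.genes[15]
    chain_model.reactions[1].gpr = parse_gpr(g)
    envelope = fva(chain_model)
    i = m.index(g)
    prev_mag = None
    for shift in (0.0, -1.0, -2.0, -4.0, -8.0):
        y = m.y_wt.copy()
        y[i] += shift - (3 * m.sigma_wt[i] if shift else 0.0)
        out = trame_bounds(envelope, chain_model, y, m)
        mag = abs(out["R1"][1])
        if prev_mag is not None:
            assert mag <= prev_mag + 1e-12
        prev_mag = mag


def test_negative_vmin_scales_magnitude(fitted_model):
    m = fitted_model
    g = m.genes[15]
    model = MetabolicModelFile(
        ["A", "B"],
        [
            Reaction("EX_A", {"A": 1.0}, -10.0, 10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, -20.0, 20.0,
                     gpr=parse_gpr(g)),
            Reaction("BIO", {"B": -1.0}, -10.0, 10.0),
        ],
        "BIO",
    )
    envelope = FluxBounds({"EX_A": (-10, 10), "R1": (-20, 20),
                           "BIO": (-10, 10)})
    ratios_zero = expression_ratios(m.y_wt, m, TrameParams(), zero_genes=[g])
    assert ratios_zero[g] == 0.0
    out = trame_bounds(envelope, model, m.y_wt, m, zero_genes=[g])
    assert out["R1"] == (0.0, 0.0)
    assert out["EX_A"] == (-10, 10)  # no GPR: untouched


# ---------------------------------------------------------------------------
# essentiality


def test_single_path_enzymes_essential(fitted_model, toy_met):
    met, truth = toy_met
    for g in sorted(truth.essential_genes):
        assert essentiality(met, fitted_model, None, g) == "essential"


def test_isozymes_non_essential(fitted_model, toy_met):
    met, truth = toy_met
    for g in sorted(truth.isozyme_genes):
        assert essentiality(met, fitted_model, None, g) == "non_essential"


def test_gene_without_effect_path_non_essential(fitted_model, toy_met):
    met, truth = toy_met
    gpr_genes = met.genes()
    # a non-TF gene outside every GPR has no route to the flux layer
    for g in fitted_model.genes:
        if g not in gpr_genes and g not in fitted_model.tf_set:
            assert essentiality(met, fitted_model, None, g) == "non_essential"
            break
    else:
        pytest.skip("all genes appear in GPRs")


def test_unknown_gene_rejected(fitted_model, toy_met):
    met, _ = toy_met
    with pytest.raises(KeyError):
        essentiality(met, fitted_model, None, "not_a_gene")


def test_gpr_only_gene_branch(fitted_model, toy_met):
    _, _ = toy_met
    # model whose enzyme gene is not in the regulatory model at all
    model = MetabolicModelFile(
        ["A", "B"],
        [
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                     gpr=parse_gpr("orphan_enzyme")),
            Reaction("BIO", {"B": -1.0}, 0.0, 1000.0),
        ],
        "BIO",
    )
    assert essentiality(model, fitted_model, None, "orphan_enzyme") \
        == "essential"
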