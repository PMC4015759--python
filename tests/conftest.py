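import itertools

import pytest

from federank import (
    JoinSpec,
    Registry,
    fig1_registry,
    load_pax_fixture,
)
from federank.scoring import ranking_sort_key
from federank.service_model import Role


@pytest.fixture()
def registry() -> Registry:
    return fig1_registry()


@pytest.fixture()
def pax_world():
    return load_pax_fixture()


def brute_force_connections(reg: Registry):
    """Independent enumeration of interface-level connections.

    Checks every (pattern, source interface, target interface) triple
    directly against the role constraints, without going through the
    registry's derivation logic.
    """
    found = []
    for cp_name in sorted(reg.connection_patterns):
        cp = reg.connection_patterns[cp_name]
        for si, ti in itertools.product(sorted(reg.interfaces), sorted(reg.interfaces)):
            if si == ti:
                continue
            si_ap = reg.access_patterns[reg.interfaces[si].access_pattern]
            ti_ap = reg.access_patterns[reg.interfaces[ti].access_pattern]
            if si_ap.mart != cp.source_mart or ti_ap.mart != cp.target_mart:
                continue
            good = True
            for c in cp.clauses:
                src_role = si_ap.roles.get(c.source)
                tgt_role = ti_ap.roles.get(c.target)
                if src_role not in (Role.OUTPUT, Role.OUTPUT_RANKED, Role.INPUT_OUTPUT):
                    good = False
                if tgt_role not in (Role.INPUT, Role.INPUT_OUTPUT):
                    good = False
            if good:
                found.append((cp_name, si, ti))
    return found


def cartesian_join(streams, joins, weights):
    """Definitional join semantics by exhaustive cartesian enumeration.

    Only usable on tiny instances; independent of the engine's hash-join
    and threshold paths (re-derives scores from the raw ranked values).
    """
    from federank.rank_join import passthrough_tuples, _merge, _left_key, _right_key

    ranked = [s.interface for s in streams if s.ranked_attribute is not None]
    eff = weights.effective_weights([n for n in ranked if n in weights.weights])
    parts = [passthrough_tuples(s, weights, eff) for s in streams]
    out = []
    for combo in itertools.product(*parts):
        tup = combo[0]
        ok = True
        for t, specs in zip(combo[1:], joins):
            key = _left_key(tup, specs)
            iface = next(iter(t.records))
            if _right_key(t.records[iface], specs, iface) != key:
                ok = False
                break
            tup = _merge(tup, t, key)
        if ok:
            out.append(tup)
    return sorted(out, key=ranking_sort_key)


def assert_same_ranking(a, b):
    """Same tuples in the same order (by provenance and score)."""
    assert [t.provenance for t in a] == [t.provenance for t in b]
    for x, y in zip(a, b):
        assert x.global_score == pytest.approx(y.global_score, abs=1e-12)
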