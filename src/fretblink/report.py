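"""Derived photophysical quantities from reference constants.

The packaged ``data/reference_values.json`` file stores the measured
photophysical constants of the two FRET pairs this package targets
(mEos3.2-JF646 and PA-JF549-JF646): amplitude-weighted mean lifetimes
with and without the acceptor, steady-state FRET efficiencies, Förster
radii, photon budgets, switching-event counts and localization
precisions.  :func:`photophysics_report` recomputes every closed-form
quantity that follows from them — lifetime-based FRET efficiency,
donor-acceptor distance, lifetime ratio, photon-budget fold change —
through the package's own FRET math.
"""

from __future__ import annotations

from importlib import resources

from . import fret_core

__all__ = ["load_reference_values", "photophysics_report"]


def load_reference_values() -> dict:
    """Load the packaged reference photophysical constants."""
    import json

    path = resources.files("fretblink").joinpath("data/reference_values.json")
    return json.loads(path.read_text())


def photophysics_report(values: dict | None = None) -> dict:
    """Recompute all derived quantities from reference constants.

    For every pair: FRET efficiency from the lifetime pair (raw and
    rounded to 2 decimals), the donor-acceptor distance from the stated
    efficiency and Förster radius (raw nm and nearest nm), the donor
    lifetime ratio, and — where photon budgets exist — the fold change in
    photon budget.
    """
    values = values or load_reference_values()
    report: dict = {}
    for pair, v in values.items():
        entry: dict = {}
        tau_d = v.get("tau_donor_ns")
        tau_da = v.get("tau_donor_acceptor_ns")
        if tau_d and tau_da:
            e = fret_core.efficiency_from_lifetime(tau_d, tau_da)
            entry["efficiency_from_lifetime"] = e
            entry["efficiency_from_lifetime_2dp"] = round(e, 2)
            entry["lifetime_ratio"] = tau_d / tau_da
        e_ref = v.get("fret_efficiency")
        r0 = v.get("forster_radius_nm")
        if e_ref and r0:
            r = fret_core.distance_from_efficiency(e_ref, r0)
            entry["distance_nm"] = r
            entry["distance_nm_rounded"] = round(r)
            entry["efficiency_at_r0"] = fret_core.efficiency_from_distance(r0, r0)
        b_d = v.get("photon_budget_donor")
        b_p = v.get("photon_budget_pair")
        if b_d and b_p:
            entry["photon_budget_ratio"] = b_p / b_d
        report[pair] = entry
    return report
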