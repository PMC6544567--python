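"""Evaluate the 17 rule-based structural damage features on a model triple.

Sixteen features contribute to the overall "structurally damaging" verdict;
the seventeenth ("exposed hydrophobic introduced") is evaluated and reported
but never used, having shown no discriminatory value.  Burial is assessed on
the wild-type structure (RSA < 9%); the mutant RSA enters only the
buried/exposed-switch feature.  The three interaction features (disulfide,
H-bond, salt bridge) are excluded from the comparison whenever the
WT-CONTROL repack already changes them — such differences are artefacts of
repacking, not of the substitution.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any, Optional

from .config import DEFAULT_CONFIG, RunConfig
from .structure_io import Structure, VariantSpec
from .geometry import (backbone_torsions, is_buried, rama_classify,
                       residue_rama_class, sasa_profile)
from .secondary_structure import assign_secondary_structure, ss_changed_at
from .interactions import interaction_set_for
from .mutant_builder import ModelTriple, control_excluded_features
from .clash_cavity import (cavity_feature, cavity_volumes, clash_feature,
                           local_clash_score)

__all__ = ["FEATURES", "USED_FEATURES", "WT_DEPENDENT_FEATURES", "ResidueClass",
           "AlertReport", "evaluate", "residue_class"]

FEATURES: tuple[str, ...] = (
    "disulfide_breakage",
    "buried_pro_introduced",
    "clash",
    "buried_hydrophilic_introduced",
    "buried_charge_introduced",
    "buried_charge_switch",
    "secondary_structure_altered",
    "buried_charge_replaced",
    "disallowed_phi_psi",
    "buried_gly_replaced",
    "buried_hbond_breakage",
    "buried_saltbridge_breakage",
    "cavity_altered",
    "buried_exposed_switch",
    "cis_pro_replaced",
    "gly_in_bend",
    "exposed_hydrophobic_introduced",
)
#: the report-only feature never contributes to the overall verdict
UNUSED_FEATURES: frozenset[str] = frozenset({"exposed_hydrophobic_introduced"})
USED_FEATURES: tuple[str, ...] = tuple(f for f in FEATURES if f not in UNUSED_FEATURES)

#: features whose outcome depends only on the wild-type structure
WT_DEPENDENT_FEATURES: frozenset[str] = frozenset({
    "disulfide_breakage", "buried_pro_introduced", "buried_hydrophilic_introduced",
    "buried_charge_introduced", "buried_charge_switch", "disallowed_phi_psi",
    "buried_charge_replaced", "buried_gly_replaced", "cis_pro_replaced",
    "gly_in_bend",
})

#: the three distance features subject to the WT-CONTROL exclusion
CONTROL_FEATURES = {"disulfide_breakage": "disulfide",
                    "buried_hbond_breakage": "hbond",
                    "buried_saltbridge_breakage": "saltbridge"}

HYDROPHOBIC = set("ACFILMVW")
HYDROPHILIC = set("DEHKNQR")
NEUTRAL = set("GPSTY")
NEGATIVE = set("DE")
POSITIVE = set("HKR")


@dataclasses.dataclass(frozen=True)
class ResidueClass:
    """Hydrophobicity and charge class of an amino acid (1-letter)."""

    aa: str
    hydrophobicity: str  # hydrophobic | hydrophilic | neutral
    charge: str          # "+", "-", "0"


def residue_class(aa: str) -> ResidueClass:
    if aa in HYDROPHOBIC:
        h = "hydrophobic"
    elif aa in HYDROPHILIC:
        h = "hydrophilic"
    elif aa in NEUTRAL:
        h = "neutral"
    else:
        raise ValueError(f"unknown amino acid {aa!r}")
    c = "+" if aa in POSITIVE else "-" if aa in NEGATIVE else "0"
    return ResidueClass(aa, h, c)


FIRED, CLEAR, EXCLUDED, NA = "fired", "clear", "excluded_by_control", "not_applicable"


@dataclasses.dataclass
class AlertReport:
    """Per-feature verdicts with supporting evidence for one variant."""

    variant: VariantSpec
    target: tuple                                # res_id
    verdicts: dict[str, str]
    evidence: dict[str, dict[str, Any]]
    control_excluded: set[str]

    @property
    def damaging(self) -> bool:
        return any(self.verdicts[f] == FIRED for f in USED_FEATURES)

    def fired_features(self) -> list[str]:
        return [f for f in FEATURES if self.verdicts[f] == FIRED]

    def to_json(self) -> str:
        payload = {
            "variant": {"chain": self.variant.chain_id, "position": self.variant.position,
                        "wt": self.variant.wt, "mut": self.variant.mut,
                        "frame": self.variant.frame},
            "target_residue": {"chain": self.target[0], "seqnum": self.target[1],
                               "icode": self.target[2]},
            "damaging": self.damaging,
            "features": {f: {"verdict": self.verdicts[f],
                             "wt_dependent": f in WT_DEPENDENT_FEATURES,
                             "used": f not in UNUSED_FEATURES,
                             "evidence": self.evidence.get(f, {})}
                         for f in FEATURES},
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)

    def to_text(self) -> str:
        lines = [f"Variant {self.variant.wt}{self.variant.position}{self.variant.mut} "
                 f"(chain {self.variant.chain_id}, {self.variant.frame} numbering)",
                 f"Overall: {'structurally DAMAGING' if self.damaging else 'no structural alert'}",
                 ""]
        for f in FEATURES:
            tag = {FIRED: "ALERT", CLEAR: "  ok ", EXCLUDED: "excl.", NA: " n/a "}[self.verdicts[f]]
            note = " (evaluated, not used)" if f in UNUSED_FEATURES else ""
            lines.append(f"[{tag}] {f.replace('_', ' ')}{note}")
            ev = self.evidence.get(f)
            if ev and self.verdicts[f] == FIRED:
                detail = ", ".join(f"{k}={_fmt(v)}" for k, v in sorted(ev.items()))
                lines.append(f"        {detail}")
        return "\n".join(lines) + "\n"


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)


def evaluate(models: ModelTriple, v: VariantSpec,
             config: RunConfig = DEFAULT_CONFIG,
             input_structure: Optional[Structure] = None) -> AlertReport:
    """Apply all 17 feature rules to a WT / MUTANT / WT-CONTROL triple."""
    wt, mut = models.wt, models.mutant
    rid = models.zone.target
    wt_res = wt.get_residue(*rid)
    mut_res = mut.get_residue(*rid)
    wt_aa, mut_aa = v.wt, v.mut
    wt_cls, mut_cls = residue_class(wt_aa), residue_class(mut_aa)

    verdicts: dict[str, str] = {}
    evidence: dict[str, dict[str, Any]] = {}

    # ---- substrates -------------------------------------------------------
    wt_sasa = sasa_profile(wt, probe=config.sasa_probe, points=config.sasa_points)
    mut_sasa = sasa_profile(mut, probe=config.sasa_probe, points=config.sasa_points)
    rsa_wt = wt_sasa.rsa.get(rid)
    rsa_mut = mut_sasa.rsa.get(rid)
    buried = is_buried(rsa_wt, config.rsa_buried) if rsa_wt is not None else None

    torsions = backbone_torsions(wt)
    phi, psi = torsions.phi.get(rid), torsions.psi.get(rid)
    omega = torsions.omega.get(rid)

    ss_wt = assign_secondary_structure(wt)
    ss_mut = assign_secondary_structure(mut)

    inter_wt = interaction_set_for(wt, wt_res, config.disulfide_cutoff,
                                   config.hbond_cutoff, config.saltbridge_cutoff)
    inter_mut = interaction_set_for(mut, mut_res, config.disulfide_cutoff,
                                    config.hbond_cutoff, config.saltbridge_cutoff)
    excluded = control_excluded_features(wt, models.wt_control, rid, config)

    clash_wt = local_clash_score(wt, wt_res, config)
    clash_mut = local_clash_score(mut, mut_res, config)
    cav_wt = cavity_volumes(wt, config=config)
    cav_mut = cavity_volumes(mut, config=config)

    def set_verdict(name: str, fired: Optional[bool], ev: dict[str, Any]) -> None:
        if fired is None:
            verdicts[name] = NA
        else:
            verdicts[name] = FIRED if fired else CLEAR
        evidence[name] = ev

    # ---- 1 disulfide breakage --------------------------------------------
    wt_ss_bonds = inter_wt.disulfides
    fired = bool(wt_ss_bonds) and not inter_mut.disulfides
    set_verdict("disulfide_breakage", fired,
                {"wt_disulfides": [(d.res_a, d.res_b, round(d.distance, 2))
                                   for d in wt_ss_bonds],
                 "mutant_disulfides": [(d.res_a, d.res_b, round(d.distance, 2))
                                       for d in inter_mut.disulfides]})
    if "disulfide" in excluded:
        verdicts["disulfide_breakage"] = EXCLUDED

    # ---- 2 buried Pro introduced -----------------------------------------
    set_verdict("buried_pro_introduced",
                None if buried is None else
                (buried and mut_aa == "P" and wt_aa != "P"),
                {"rsa_wt": rsa_wt, "buried": buried})

    # ---- 3 clash ----------------------------------------------------------
    set_verdict("clash", clash_feature(clash_wt, clash_mut, config),
                {"clash_score_wt": clash_wt.score, "clash_score_mut": clash_mut.score,
                 "n_local_atoms": clash_mut.n_local_atoms})

    # ---- 4 buried hydrophilic introduced ----------------------------------
    set_verdict("buried_hydrophilic_introduced",
                None if buried is None else
                (buried and wt_cls.hydrophobicity == "hydrophobic"
                 and mut_cls.hydrophobicity == "hydrophilic"),
                {"rsa_wt": rsa_wt, "wt_class": wt_cls.hydrophobicity,
                 "mut_class": mut_cls.hydrophobicity})

    # ---- 5 buried charge introduced ---------------------------------------
    set_verdict("buried_charge_introduced",
                None if buried is None else
                (buried and wt_cls.charge == "0" and mut_cls.charge != "0"),
                {"rsa_wt": rsa_wt, "wt_charge": wt_cls.charge, "mut_charge": mut_cls.charge})

    # ---- 6 buried charge switch -------------------------------------------
    set_verdict("buried_charge_switch",
                None if buried is None else
                (buried and wt_cls.charge != "0" and mut_cls.charge != "0"
                 and wt_cls.charge != mut_cls.charge),
                {"rsa_wt": rsa_wt, "wt_charge": wt_cls.charge, "mut_charge": mut_cls.charge})

    # ---- 7 secondary structure altered ------------------------------------
    set_verdict("secondary_structure_altered", ss_changed_at(ss_wt, ss_mut, rid),
                {"ss_wt": ss_wt.at(rid), "ss_mut": ss_mut.at(rid)})

    # ---- 8 buried charge replaced -----------------------------------------
    set_verdict("buried_charge_replaced",
                None if buried is None else
                (buried and wt_cls.charge != "0" and mut_cls.charge == "0"),
                {"rsa_wt": rsa_wt, "wt_charge": wt_cls.charge, "mut_charge": mut_cls.charge})

    # ---- 9 disallowed phi/psi ---------------------------------------------
    if phi is None or psi is None:
        set_verdict("disallowed_phi_psi", None, {"phi": phi, "psi": psi})
    else:
        next_aa = _next_residue_aa(wt, rid)
        input_s = input_structure if input_structure is not None else wt
        input_tors = backbone_torsions(input_s)
        iphi = input_tors.phi.get(rid, phi)
        ipsi = input_tors.psi.get(rid, psi)
        wt_class_name = residue_rama_class(wt_aa, next_aa)
        mut_class_name = residue_rama_class(mut_aa, next_aa)
        rama_input = rama_classify(iphi if iphi is not None else phi,
                                   ipsi if ipsi is not None else psi, wt_class_name)
        rama_wt = rama_classify(phi, psi, wt_class_name)
        rama_mut = rama_classify(phi, psi, mut_class_name)
        fired = (rama_mut.is_outlier and not rama_wt.is_outlier
                 and not rama_input.is_outlier)
        set_verdict("disallowed_phi_psi", fired,
                    {"phi": phi, "psi": psi, "rama_wt": rama_wt.category,
                     "rama_input": rama_input.category, "rama_mut": rama_mut.category,
                     "wt_table": wt_class_name, "mut_table": mut_class_name})

    # ---- 10 buried Gly replaced -------------------------------------------
    set_verdict("buried_gly_replaced",
                None if buried is None else
                (buried and wt_aa == "G" and mut_aa != "G"),
                {"rsa_wt": rsa_wt, "wt": wt_aa})

    # ---- 11 buried H-bond breakage ----------------------------------------
    fired = (bool(buried) and bool(inter_wt.hbonds) and not inter_mut.hbonds) \
        if buried is not None else None
    set_verdict("buried_hbond_breakage", fired,
                {"rsa_wt": rsa_wt,
                 "wt_hbonds": len(inter_wt.hbonds), "mut_hbonds": len(inter_mut.hbonds)})
    if "hbond" in excluded:
        verdicts["buried_hbond_breakage"] = EXCLUDED

    # ---- 12 buried salt bridge breakage -----------------------------------
    fired = (bool(buried) and bool(inter_wt.saltbridges)
             and not inter_mut.saltbridges) if buried is not None else None
    set_verdict("buried_saltbridge_breakage", fired,
                {"rsa_wt": rsa_wt,
                 "wt_saltbridges": [(b.pos_res, b.pos_atom, b.neg_res, b.neg_atom,
                                     round(b.distance, 2)) for b in inter_wt.saltbridges],
                 "mut_saltbridges": len(inter_mut.saltbridges)})
    if "saltbridge" in excluded:
        verdicts["buried_saltbridge_breakage"] = EXCLUDED

    # ---- 13 cavity altered -------------------------------------------------
    set_verdict("cavity_altered", cavity_feature(cav_wt, cav_mut, config),
                {"cavity_total_wt": cav_wt.total, "cavity_total_mut": cav_mut.total})

    # ---- 14 buried/exposed switch ------------------------------------------
    if rsa_wt is None or rsa_mut is None:
        set_verdict("buried_exposed_switch", None, {"rsa_wt": rsa_wt, "rsa_mut": rsa_mut})
    else:
        b_wt = is_buried(rsa_wt, config.rsa_buried)
        b_mut = is_buried(rsa_mut, config.rsa_buried)
        set_verdict("buried_exposed_switch",
                    b_wt != b_mut and abs(rsa_wt - rsa_mut) >= config.rsa_switch_delta,
                    {"rsa_wt": rsa_wt, "rsa_mut": rsa_mut})

    # ---- 15 cis Pro replaced ------------------------------------------------
    if wt_aa != "P":
        set_verdict("cis_pro_replaced", False, {"wt": wt_aa})
    elif omega is None:
        set_verdict("cis_pro_replaced", None, {"omega": None})
    else:
        set_verdict("cis_pro_replaced",
                    abs(omega) <= config.cis_omega_max and mut_aa != "P",
                    {"omega": omega})

    # ---- 16 Gly in a bend ----------------------------------------------------
    set_verdict("gly_in_bend",
                wt_aa == "G" and mut_aa != "G" and ss_wt.at(rid) == "S",
                {"ss_wt": ss_wt.at(rid)})

    # ---- 17 exposed hydrophobic introduced (report-only) ---------------------
    set_verdict("exposed_hydrophobic_introduced",
                None if buried is None else
                (not buried and wt_cls.hydrophobicity == "hydrophilic"
                 and mut_cls.hydrophobicity == "hydrophobic"),
                {"rsa_wt": rsa_wt, "wt_class": wt_cls.hydrophobicity,
                 "mut_class": mut_cls.hydrophobicity})

    return AlertReport(v, rid, verdicts, evidence, excluded)


def _next_residue_aa(s: Structure, rid: tuple) -> Optional[str]:
    chain = [r for r in s.chains.get(rid[0], ()) if not r.het and r.one_letter is not None]
    for k, r in enumerate(chain):
        if r.res_id == rid:
            if k + 1 < len(chain):
                return chain[k + 1].one_letter
            return None
    return None
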