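"""The hierarchical scoring scheme and its published scale maxima.

Loads the packaged default scheme, shows its structure, and scores a
best-case street side to demonstrate the item -> sub-scale -> section
roll-up.  The grand maximum (210) is the sum of the positive section caps;
cross-domain sub-scales (27 / 22 / 11) sum member-item maxima across
sections.
"""
from mapssn.audit_model import AuditRecord, load_scheme
from mapssn.scoring import score_unit, unit_section_score

scheme = load_scheme()
print(f"scheme {scheme.name!r}: {len(scheme.items)} items,"
      f" {len(scheme.subscales)} sub-scales")
print("grand maximum:", scheme.best_case_grand_score())
for name in scheme.cross_domain:
    print(f"  cross-domain {name}: max {scheme.best_case_cross_domain(name)}")

# a best-case segment side: every positive item at its best recode
values = {}
for item in scheme.items_for("segment_side"):
    sub = scheme.subscale_of(item.name)
    values[item.name] = item.best_raw if sub.valence == "positive" \
        else item.worst_raw
record = AuditRecord(unit_kind="segment_side", unit_id="S01.R0.01.O",
                     school_id="S01", item_values=values)
for name, s in score_unit(record, scheme).items():
    print(f"  {name}: raw {s.raw_sum}, capped {s.capped} (sign {s.sign:+d})")
print("segment section score:",
      unit_section_score(record, scheme, "segment"))
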