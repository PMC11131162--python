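"""Quality-control screening of a family-history registry.

Generates a clean synthetic pedigree, plants one anomaly of each kind, and
runs the QC report.  Each alert names an atypical-but-possible kinship
pattern whose presence usually indicates a data-entry mistake worth
double-checking (the alerts are non-normative).
"""

from kinqc import generate_clean, inject, qc_report
from kinqc.unusual import ALERT_KINDS

fb = generate_clean(seed=11)
print(f"clean pedigree: {len(fb.persons)} persons, "
      f"{len(fb.marriage_bonds)} marriage bonds")
print("alerts on the clean pedigree:", sum(qc_report(fb).counts[k] for k in ALERT_KINDS))

for kind in ALERT_KINDS:
    dirty, manifest = inject(fb, seed=5, kind=kind, count=1)
    report = qc_report(dirty)
    [alert] = [a for a in report.alerts if a.kind == kind]
    print(f"\ninjected {kind}:")
    print(f"  detector says: {alert.note}")
    print(f"  participants {alert.participants} match the injection manifest:",
          list(alert.participants) in [list(t) for t in manifest.expected_alerts()[kind]])
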