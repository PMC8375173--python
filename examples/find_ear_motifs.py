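"""Detect EAR-like repressor boxes and report their position relative to the fingers.

Plants a DLNxxP EAR motif in the N-terminal flank and an FDLNI EAR-like motif
after the last finger, then recovers both with the shipped box library.
"""

from zfsurvey import find_boxes, scan_domains
from zfsurvey.accessory_motifs import hits_to_table
from zfsurvey.synthetic_data import ProteinSpec, make_protein

record, _, planted = make_protein(ProteinSpec(
    "demo.1", domain_types=("Q",), gaps=(), n_flank=15, c_flank=15,
    planted_boxes=(("EAR-DLNxxP", "N-of-first-ZF"), ("EAR-FDLNI", "C-of-last-ZF")),
    seed=3,
))
print(f"planted: {[(p.name, p.start, p.end) for p in planted]}\n")

hits = find_boxes(record, scan_domains(record))
print(hits_to_table(hits).to_string(index=False))
print("\n# context_observed places each box relative to the zinc fingers;")
print("# an EAR box N-terminal of the finger is a classic repression-domain layout.")
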