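"""Predict mature neuropeptides from precursor proteins.

Scans three canonical precursor layouts: an HFRIamide-style precursor
(peptide-glycine cassettes between KR sites), a pyroGlu-YFamide-style
precursor (glutamine-initial cassettes), and an IPYFAN tandem-repeat
precursor without the amidation glycine.
"""

from planaxis.neuropeptides import PrecursorProtein, scan_precursor

precursors = [
    PrecursorProtein("pp-HFRI", "M" + "L" * 19 + "KRHFRIGKRHFRIGKRHFRIGKR",
                     has_signal_peptide=True, signal_cleavage_pos=20),
    PrecursorProtein("pp-QYF", "M" + "L" * 19 + "KRQYFGKRQYFGKR",
                     has_signal_peptide=True, signal_cleavage_pos=20),
    PrecursorProtein("pp-IPYFAN", "M" + "L" * 19 + "KR" + "IPYFANKR" * 5,
                     has_signal_peptide=True, signal_cleavage_pos=20),
]
for p in precursors:
    report = scan_precursor(p)
    products = [
        f"{x.peptide}{'-amide' if x.amidated else ''}"
        f"{' (pyroGlu)' if x.pyro_glu else ''}"
        for x in report.products
    ]
    motif = f"  repeat motif {report.repeat_motif[0]} x{report.repeat_motif[1]}" \
        if report.repeat_motif else ""
    print(f"{p.id}: {len(report.sites)} dibasic sites -> {products}"
          f"{motif}  neuropeptide-like: {report.neuropeptide_like}")
print("a terminal glycine before a cleavage site marks C-terminal amidation; "
      "a leading glutamine marks pyroglutamate cyclization.")
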