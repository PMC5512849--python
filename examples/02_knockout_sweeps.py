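"""DO sweeps for the wild type and the fnr/arcA regulator knockouts.

Simulates batch cultures across 0-8% DO for each strain and reports the
lactate profile and its peak. Losing Fnr removes succinate (no fumarate
reductase activation) and lets lactate pile up at very low DO; losing ArcA
keeps pyruvate dehydrogenase running, which feeds NADH and acetyl-CoA into
ethanol, so the arcA knockout out-produces the wild type in ethanol.
"""

import aeroferm as af

grid = list(range(0, 9))
for strain in ("WT", "fnr", "arcA"):
    sweep = af.do_sweep(strain, grid)
    table = sweep.table
    lactate = ", ".join(f"{do:.0f}%:{lac:.2f}" for do, lac in
                        zip(table["DO_percent"], table["lactate"]))
    print(f"\n{strain}: lactate (g/l) vs DO -> {lactate}")
    peak = af.find_peak(sweep, "lactate")
    if peak["interior"]:
        print(f"  interior lactate peak at DO = {peak['DO_percent']:.0f}% "
              f"({peak['value']:.2f} g/l)")
    else:
        print("  no interior lactate peak on this grid")
    print(f"  ethanol at 3% DO: {table.set_index('DO_percent').loc[3.0, 'ethanol']:.2f} g/l; "
          f"succinate at 1% DO: {table.set_index('DO_percent').loc[1.0, 'succinate']:.3f} g/l")
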