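"""Derive the mechanistic model parameters from observed quantities.

Walks the closed-form derivation chain: filtration clearances from plasma
binding and GFR, secretion clearance by filtration subtraction, equilibrium
partition coefficients from steady-state tissue ratios, the retrograde
well-stirred hepatic intrinsic clearance, and the basolateral uptake
clearances via the Kp,uu chain. Writes the audit report as JSON.
"""

from pathlib import Path

from pbpkddi.pipeline import reference_derivation

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rep = reference_derivation()
    width = max(len(k) for k in rep.values)
    for name, value in rep.values.items():
        unit = rep.units[name]
        print(f"{name:<{width}}  {value:10.4g}  {unit}")
    OUT.mkdir(exist_ok=True)
    rep.to_json(OUT / "derived_parameters.json")
    print(f"\nwrote {OUT / 'derived_parameters.json'}")


if __name__ == "__main__":
    main()
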