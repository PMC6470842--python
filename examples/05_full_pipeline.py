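"""Run every pipeline stage end to end and list the written outputs.

Equivalent to a command-line driver invocation with the default
configuration: derive, simulate (both arms), nca, ddi, sweep, synth.
"""

from pathlib import Path

from pbpkddi.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main() -> None:
    results = run_pipeline(outdir=OUT)
    print(results["nca"][["arm", "compound", "CL", "CL_R",
                          "Xe_0_24_pct"]].round(2).to_string(index=False))
    rep = results["ddi"]
    print({k: round(v, 3) for k, v in rep.auc_ratio.items()})
    print("outputs:")
    for name in results["manifest"]["outputs"]:
        print(f"  {OUT / name}")


if __name__ == "__main__":
    main()
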