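"""Run the entire analysis end to end and write a report.

With no input paths configured the pipeline simulates the community from
the seed; point the config at CSV files (agonistic matrix, visitation
matrix, trait tables) to analyse real data instead.  Reduced search
budgets keep this example quick; the defaults (n_runs = 50,
n_null = 100) are the study settings.
"""

from dominet.pipeline import RunConfig, run_reproduce

config = RunConfig(seed=0, n_runs=10, n_null=20, out_dir="scratch/example_run")
report = run_reproduce(config)

ts = report["tournament_summary"]["rounded"]
nw = report["network"]
print(f"contests per species {ts['per_individual']}, per dyad {ts['per_dyad']}")
print(f"Q = {nw['rounded']['Q']}, z = {nw['rounded']['z']}, CPness = {nw['cpness']:.3f}")
print(f"GAM deviance explained = {report['gam']['deviance_explained_pct']:.1f}%")
for name, reg in report["regressions"].items():
    if reg:
        print(f"{name}: R2 = {reg['rounded']['r_squared']}")
print("full JSON + text report in scratch/example_run/")
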