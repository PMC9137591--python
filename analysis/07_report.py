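"""Run the full pipeline end-to-end in one call and render the markdown
report (the per-stage scripts 01-06 show the same computations step by
step; this driver exercises the single-command path).
"""

from gutlinks.io import Config
from gutlinks.pipeline import make_report, run_pipeline

OUT = "results/analysis_full"


def main():
    run_pipeline(Config(), OUT, design=True)
    text = make_report(OUT)
    print(text)


if __name__ == "__main__":
    main()
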