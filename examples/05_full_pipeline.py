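"""Run the complete decoding benchmark: PGMs -> decoder -> identification.

Generates the desk-scale synthetic benchmark (3 subjects, 50 categories x 8
images, shared + individual latent structure, distractor visual variance),
then runs the cross-validated pipeline for the combined decoder and its two
single-block ablations.  The combined decoder should win: shared features
pool evidence across subjects, individual features add subject-specific
stimulus information.
"""

from mspgm import PipelineConfig, gen_decoding_benchmark, run_pipeline

dataset = gen_decoding_benchmark(seed=0)
config = PipelineConfig(d_com=8, d_ind=8, seed=0)
report = run_pipeline(dataset, config)

print(f"{dataset.n_samples} samples, {report['n_validation']} held out for "
      f"penalty selection, {config.n_folds}-fold cross-validation\n")
for variant, block in report["variants"].items():
    per_subj = ", ".join(
        f"{sid}={score:.3f}" for sid, score in block["per_subject_mean"].items()
    )
    print(f"{variant:16s} mean S = {block['mean_score']:.4f}  ({per_subj})")

print(
    "\nMean S is the confidence category score averaged over test samples,\n"
    "folds and subjects (1 = true category always ranks first, 0.5 = chance).\n"
    "The combined decoder outscoring both ablations is the method's point:\n"
    "shared and individual features carry complementary information."
)
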