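{
  "motifs": [
    {
      "id": "osc_negative_loop",
      "class": "oscillation",
      "file": "osc_negative_loop.tsv",
      "min_size": 3,
      "note": "Two-component negative feedback loop; pure delayed negative feedback oscillates only with >=3 components, hence the minimum realized size."
    },
    {
      "id": "osc_negative_selfloop",
      "class": "oscillation",
      "file": "osc_negative_selfloop.tsv",
      "min_size": 3,
      "note": "Negative self-regulation: the compressed form of a longer negative feedback cycle collapsed onto one node."
    },
    {
      "id": "osc_amplified_negative_feedback",
      "class": "oscillation",
      "file": "osc_amplified_negative_feedback.tsv",
      "min_size": null,
      "note": "Relaxation oscillator: self-amplifying activator embedded in a negative loop."
    },
    {
      "id": "osc_substrate_depletion",
      "class": "oscillation",
      "file": "osc_substrate_depletion.tsv",
      "min_size": null,
      "note": "Substrate-depletion oscillator: self-amplifying responder that inhibits its activator."
    },
    {
      "id": "adapt_nfblb",
      "class": "adaptation",
      "file": "adapt_nfblb.tsv",
      "min_size": null,
      "note": "Negative feedback loop with a buffering node (input node A, output C, buffer B)."
    },
    {
      "id": "adapt_nfblb_alt",
      "class": "adaptation",
      "file": "adapt_nfblb_alt.tsv",
      "min_size": null,
      "note": "Buffered negative feedback with the inhibitory arm on the output-to-buffer edge."
    },
    {
      "id": "adapt_ifflp",
      "class": "adaptation",
      "file": "adapt_ifflp.tsv",
      "min_size": null,
      "note": "Incoherent feedforward loop with a proportioner node; direct and indirect arms oppose."
    },
    {
      "id": "adapt_ifflp_alt",
      "class": "adaptation",
      "file": "adapt_ifflp_alt.tsv",
      "min_size": null,
      "note": "Incoherent feedforward loop with the inhibition on the input-to-proportioner edge."
    },
    {
      "id": "bist_mutual_activation",
      "class": "bistable_switch",
      "file": "bist_mutual_activation.tsv",
      "min_size": null,
      "note": "Mutual activation: a two-component positive feedback loop."
    },
    {
      "id": "bist_mutual_inhibition",
      "class": "bistable_switch",
      "file": "bist_mutual_inhibition.tsv",
      "min_size": null,
      "note": "Mutual inhibition (double-negative feedback): a toggle switch."
    },
    {
      "id": "bist_positive_selfloop",
      "class": "bistable_switch",
      "file": "bist_positive_selfloop.tsv",
      "min_size": null,
      "note": "Positive self-regulation: compressed form of a longer positive feedback cycle."
    },
    {
      "id": "bist_coupled_activation",
      "class": "bistable_switch",
      "file": "bist_coupled_activation.tsv",
      "min_size": null,
      "note": "Coupled positive feedback: mutual activation with an additional self-activation."
    },
    {
      "id": "bist_toggle_selfactivation",
      "class": "bistable_switch",
      "file": "bist_toggle_selfactivation.tsv",
      "min_size": null,
      "note": "Mutual inhibition reinforced by self-activation of one component."
    }
  ]
}
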