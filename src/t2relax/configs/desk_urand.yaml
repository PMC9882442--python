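# Desk-scale smoke configuration: pixel-random corpus, two fitting methods
# and one supervised 1D network. Completes in well under a minute on one CPU.
seed: 7
data:
  style: urand
  shape: [16, 16]
  n_train: 24
  n_test: 5
methods: [loglin, nlls]
networks:
  - name: nn1d_supervised
    arch: nn1d
    strategy: supervised
    epochs: 4
    batch_size: 1024
evaluation:
  noise_addition: null
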