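simulate.n_samples: 200
simulate.n_features: 120
train.model: multi_cnn
train.epochs: 40
train.kernel_size: 1
train.pool_size: 1
train.n_conv_layers: 1
train.weight_decay: 10.0
train.dropout: 0.1
train.batch_norm: false
markers.top_k: 10
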