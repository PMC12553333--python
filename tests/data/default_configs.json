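[
  {"model": "cnn", "lr": 0.0001, "dropout": 0.1, "activation": "ReLU",
   "n_heads": "", "n_layers": 3, "hidden_dim": 256, "pooling": "MaxPool1d",
   "batch_size": 32, "n_epochs": 100, "norm": ""},
  {"model": "cnn_gru", "lr": 0.0001, "dropout": 0.1, "activation": "ReLU",
   "n_heads": "", "n_layers": 2, "hidden_dim": 64, "pooling": "",
   "batch_size": 32, "n_epochs": 100, "norm": ""},
  {"model": "transformer", "lr": 0.0001, "dropout": 0.1, "activation": "ReLU",
   "n_heads": 4, "n_layers": 2, "hidden_dim": 64, "pooling": "",
   "batch_size": 32, "n_epochs": 100, "norm": "LayerNorm"},
  {"model": "gcn", "lr": 1e-05, "dropout": 0.1, "activation": "ReLU",
   "n_heads": "", "n_layers": 3, "hidden_dim": 64,
   "pooling": "Weighted Sum + Max", "batch_size": 32, "n_epochs": 100,
   "norm": "BatchNorm"},
  {"model": "gat", "lr": 1e-05, "dropout": 0.1, "activation": "ReLU",
   "n_heads": 4, "n_layers": 3, "hidden_dim": 64,
   "pooling": "Weighted Sum + Max", "batch_size": 32, "n_epochs": 100,
   "norm": ""},
  {"model": "mpnn", "lr": 1e-05, "dropout": 0.1, "activation": "ReLU",
   "n_heads": "", "n_layers": 6, "hidden_dim": 64, "pooling": "Sum + Max",
   "batch_size": 32, "n_epochs": 100, "norm": ""},
  {"model": "neuralfp", "lr": 1e-05, "dropout": 0.1, "activation": "ReLU",
   "n_heads": "", "n_layers": 3, "hidden_dim": 64, "pooling": "Sum + Max",
   "batch_size": 32, "n_epochs": 100, "norm": "BatchNorm"},
  {"model": "attentivefp", "lr": 1e-05, "dropout": 0.1, "activation": "ReLU",
   "n_heads": "", "n_layers": 3, "hidden_dim": 64,
   "pooling": "AttentiveFPReadout", "batch_size": 32, "n_epochs": 100,
   "norm": ""},
  {"model": "pagtn", "lr": 1e-05, "dropout": 0.1, "activation": "LeakyReLU",
   "n_heads": "", "n_layers": 5, "hidden_dim": 64,
   "pooling": "Weighted Sum + Max", "batch_size": 32, "n_epochs": 100,
   "norm": ""},
  {"model": "graphormer", "lr": 1e-05, "dropout": 0.1, "activation": "ReLU",
   "n_heads": 8, "n_layers": 1, "hidden_dim": 64, "pooling": "MaxPooling",
   "batch_size": 32, "n_epochs": 100, "norm": "LayerNorm"}
]
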