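{
  "models": [
    {
      "name": "BPS",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Bartolucci et al. 2020, Front Physiol 11:314",
      "parameter_checksum": null
    },
    {
      "name": "GPB",
      "tier": "required",
      "cell_type": "endocardial",
      "source": "Grandi, Pasqualini, Bers 2010, J Mol Cell Cardiol 48:112-121",
      "parameter_checksum": "00376cc8951e38d0"
    },
    {
      "name": "GPB-M",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Mann et al. 2016, J Mol Cell Cardiol 100:25-34",
      "parameter_checksum": null
    },
    {
      "name": "ORd",
      "tier": "required",
      "cell_type": "endocardial",
      "source": "O'Hara, Virag, Varro, Rudy 2011, PLoS Comput Biol 7:e1002061",
      "parameter_checksum": "53670df26c27ec2a"
    },
    {
      "name": "ORd-CiPA",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Dutta et al. 2017, Front Physiol 8:616",
      "parameter_checksum": null
    },
    {
      "name": "ORd-KM",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Krogh-Madsen et al. 2017, J Physiol",
      "parameter_checksum": null
    },
    {
      "name": "ORd-M",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Mann et al. 2016, J Mol Cell Cardiol 100:25-34",
      "parameter_checksum": null
    },
    {
      "name": "ToR-ORd",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Tomek et al. 2019, eLife 8:e48890",
      "parameter_checksum": null
    },
    {
      "name": "TNNP",
      "tier": "extended",
      "cell_type": "epicardial",
      "source": "ten Tusscher et al. 2004, Am J Physiol 286:H1573-H1589",
      "parameter_checksum": null
    },
    {
      "name": "TP",
      "tier": "required",
      "cell_type": "endocardial",
      "source": "ten Tusscher & Panfilov 2006, Am J Physiol 291:H1088-H1100",
      "parameter_checksum": "0bfa53ce37fb27b7"
    },
    {
      "name": "TP-M",
      "tier": "extended",
      "cell_type": "endocardial",
      "source": "Mann et al. 2016, J Mol Cell Cardiol 100:25-34",
      "parameter_checksum": null
    }
  ]
}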