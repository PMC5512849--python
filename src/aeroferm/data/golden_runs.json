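{
  "parameter_digest": "366c4f99768d75b3",
  "runs": {
    "WT@0": {
      "t_dep": 15.052074173800754,
      "ACE": 2.1688360732176926,
      "LAC": 0.00012317934879392447,
      "FOR": 4.425204264485275,
      "ETH": 2.4610855308934823,
      "SUC": 0.09144027147158917,
      "X": 0.7622959818933894,
      "TF_Fnr_mean": 1.0,
      "TF_ArcA_mean": 0.7919160555001791
    },
    "WT@1": {
      "t_dep": 13.581038253598578,
      "ACE": 2.317665136932361,
      "LAC": 0.00022976113052080584,
      "FOR": 4.346348846682375,
      "ETH": 2.235893473482739,
      "SUC": 0.06956657577231294,
      "X": 0.8880908599578378,
      "TF_Fnr_mean": 0.9878048780487807,
      "TF_ArcA_mean": 0.7803632422099043
    },
    "WT@3": {
      "t_dep": 11.381288668116001,
      "ACE": 2.4143771528240694,
      "LAC": 0.0018671122282522424,
      "FOR": 4.152662938483705,
      "ETH": 1.826909527014856,
      "SUC": 0.029682709446211545,
      "X": 1.1556359405047125,
      "TF_Fnr_mean": 0.5,
      "TF_ArcA_mean": 0.7775361104123675
    },
    "WT@8": {
      "t_dep": 10.09278745919927,
      "ACE": 1.663931250396531,
      "LAC": 1.5819825927425155,
      "FOR": 0.7507872918719133,
      "ETH": 0.20241575572292533,
      "SUC": 0.0042412596401385306,
      "X": 2.7067052974663652,
      "TF_Fnr_mean": 0.01939190806799138,
      "TF_ArcA_mean": 0.20206941656498978
    },
    "WT@40": {
      "t_dep": 7.561826965652489,
      "ACE": 1.704252628746929,
      "LAC": 0.5597960894353003,
      "FOR": 0.01334770690536545,
      "ETH": 0.280005049067095,
      "SUC": 0.0036395328180840124,
      "X": 3.177762708562919,
      "TF_Fnr_mean": 3.1639623902524946e-05,
      "TF_ArcA_mean": 0.07843536024375222
    },
    "fnr@0": {
      "t_dep": 19.480532279456128,
      "ACE": 0.7027060557923404,
      "LAC": 3.847307020277898,
      "FOR": 2.2289156782322603,
      "ETH": 1.6931990005667548,
      "SUC": 0.030592148934579757,
      "X": 0.6659466834638376,
      "TF_Fnr_mean": 0.0,
      "TF_ArcA_mean": 0.8767335523940056
    },
    "fnr@1": {
      "t_dep": 16.85332813818724,
      "ACE": 0.76397503298901,
      "LAC": 4.616023292482739,
      "FOR": 1.7428880378801799,
      "ETH": 1.1900616900383743,
      "SUC": 0.011631223204523176,
      "X": 0.8834010627660595,
      "TF_Fnr_mean": 0.0,
      "TF_ArcA_mean": 0.8588780949664763
    },
    "fnr@3": {
      "t_dep": 14.415947267066501,
      "ACE": 1.28501219783172,
      "LAC": 4.1945519299851215,
      "FOR": 1.5253073906689432,
      "ETH": 0.4854280112483503,
      "SUC": 0.0028399805356675626,
      "X": 1.4404342514409092,
      "TF_Fnr_mean": 0.0,
      "TF_ArcA_mean": 0.8140313979485772
    },
    "fnr@8": {
      "t_dep": 10.269407643262953,
      "ACE": 1.4633720753722737,
      "LAC": 1.841990836739172,
      "FOR": 0.2125471579383383,
      "ETH": 0.1714409279750328,
      "SUC": 0.003350223617059194,
      "X": 2.7759579675767765,
      "TF_Fnr_mean": 0.0,
      "TF_ArcA_mean": 0.18883580710748707
    },
    "fnr@40": {
      "t_dep": 7.561804286031748,
      "ACE": 1.704205221084451,
      "LAC": 0.5597891260165512,
      "FOR": 0.0132974335128325,
      "ETH": 0.27998116115554883,
      "SUC": 0.0036379867549174243,
      "X": 3.1778074720649037,
      "TF_Fnr_mean": 0.0,
      "TF_ArcA_mean": 0.07843581210680624
    },
    "arcA@0": {
      "t_dep": 17.11265687032896,
      "ACE": 1.1376803245226979,
      "LAC": 0.3870438175438369,
      "FOR": 2.8178019597734334,
      "ETH": 2.8203598013546056,
      "SUC": 0.44125038950597695,
      "X": 0.6935988067748403,
      "TF_Fnr_mean": 1.0,
      "TF_ArcA_mean": 0.0
    },
    "arcA@1": {
      "t_dep": 13.436674822311272,
      "ACE": 1.0937003098615472,
      "LAC": 0.41188716019456206,
      "FOR": 1.949737067577275,
      "ETH": 2.6768202569301076,
      "SUC": 0.37806472057943913,
      "X": 0.9962823491709892,
      "TF_Fnr_mean": 0.9878048780487808,
      "TF_ArcA_mean": 0.0
    },
    "arcA@3": {
      "t_dep": 9.84737596812531,
      "ACE": 0.9951675283169285,
      "LAC": 0.5423877858443651,
      "FOR": 0.6855490558462456,
      "ETH": 2.2549521542917574,
      "SUC": 0.14145697505959395,
      "X": 1.5929166233926106,
      "TF_Fnr_mean": 0.5,
      "TF_ArcA_mean": 0.0
    },
    "arcA@8": {
      "t_dep": 6.409437124582168,
      "ACE": 1.5665790703542506,
      "LAC": 0.12237124887115772,
      "FOR": 0.019179573650905647,
      "ETH": 0.5970194299299605,
      "SUC": 0.005001420619574517,
      "X": 3.0370397616534293,
      "TF_Fnr_mean": 0.01939190806799138,
      "TF_ArcA_mean": 0.0
    },
    "arcA@40": {
      "t_dep": 6.192960008900231,
      "ACE": 1.7185397995337928,
      "LAC": 0.06720823699463987,
      "FOR": 0.0013797099656532126,
      "ETH": 0.3609957052541557,
      "SUC": 0.003833377053569,
      "X": 3.2096409713050997,
      "TF_Fnr_mean": 3.1639623902524946e-05,
      "TF_ArcA_mean": 0.0
    },
    "pfl@0": {
      "t_dep": 61.37549247407349,
      "ACE": 0.014429671470881209,
      "LAC": 5.555531358855332,
      "FOR": 0.0,
      "ETH": 0.053046342363954675,
      "SUC": 0.3707719820569294,
      "X": 0.21807966618133057,
      "TF_Fnr_mean": 1.0,
      "TF_ArcA_mean": 0.9082132014942033
    },
    "pfl@1": {
      "t_dep": 20.007732135321827,
      "ACE": 0.14998346300636106,
      "LAC": 8.037054389592559,
      "FOR": 0.0,
      "ETH": 0.2718106376018022,
      "SUC": 0.1663319608117453,
      "X": 0.7458748166286461,
      "TF_Fnr_mean": 0.9878048780487807,
      "TF_ArcA_mean": 0.8577693995416643
    },
    "pfl@3": {
      "t_dep": 24.78524183961143,
      "ACE": 1.1973647097960698,
      "LAC": 4.5171833011780205,
      "FOR": 0.0,
      "ETH": 0.11795249648575615,
      "SUC": 0.011035736432990335,
      "X": 1.70675882842995,
      "TF_Fnr_mean": 0.5,
      "TF_ArcA_mean": 0.7655900009868511
    },
    "pfl@8": {
      "t_dep": 10.377892623389283,
      "ACE": 1.4178153719069864,
      "LAC": 1.9931263006321789,
      "FOR": 0.0,
      "ETH": 0.17096767831072837,
      "SUC": 0.0041480282773458995,
      "X": 2.7681923443923746,
      "TF_Fnr_mean": 0.019391908067991376,
      "TF_ArcA_mean": 0.1831847996567303
    },
    "pfl@40": {
      "t_dep": 7.569584219073853,
      "ACE": 1.7018983826929022,
      "LAC": 0.5656532715751216,
      "FOR": 0.0,
      "ETH": 0.27940205704996796,
      "SUC": 0.0036351475242550873,
      "X": 3.1796552948453054,
      "TF_Fnr_mean": 3.1639623902524946e-05,
      "TF_ArcA_mean": 0.07842798394495033
    }
  }
}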