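group,pattern
"Anxiety disorders",F40
"Anxiety disorders",F41
"Anxiety disorders",F93
"Depressive disorders",F32
"Depressive disorders",F33
"Depressive disorders",F34
"Suicidality or self-injury",X60
"Suicidality or self-injury",X61
"Suicidality or self-injury",X62
"Suicidality or self-injury",X63
"Suicidality or self-injury",X64
"Suicidality or self-injury",X65
"Suicidality or self-injury",X66
"Suicidality or self-injury",X67
"Suicidality or self-injury",X68
"Suicidality or self-injury",X69
"Suicidality or self-injury",X70
"Suicidality or self-injury",X71
"Suicidality or self-injury",X72
"Suicidality or self-injury",X73
"Suicidality or self-injury",X74
"Suicidality or self-injury",X75
"Suicidality or self-injury",X76
"Suicidality or self-injury",X77
"Suicidality or self-injury",X78
"Suicidality or self-injury",X79
"Suicidality or self-injury",X80
"Suicidality or self-injury",X81
"Suicidality or self-injury",X82
"Suicidality or self-injury",X83
"Suicidality or self-injury",X84
"Suicidality or self-injury",T1491
"Suicidality or self-injury",R45851
"Suicidality or self-injury",Z915
"Mental health symptoms",R450
"Mental health symptoms",R451
"Mental health symptoms",R452
"Mental health symptoms",R453
"Mental health symptoms",R454
"Mental health symptoms",R455
"Mental health symptoms",R456
"Mental health symptoms",R457
"Mental health symptoms",R46
"Trauma and stressor-related disorders",F43
"Trauma and stressor-related disorders",F94
"Eating disorders",F50
"Miscellaneous",F38
"Miscellaneous",F39
"Miscellaneous",F48
"Miscellaneous",F53
"Miscellaneous",F54
"Miscellaneous",F59
"Miscellaneous",F99
"Disruptive, impulse control, and conduct disorders",F63
"Disruptive, impulse control, and conduct disorders",F91
"Substance-related and addictive disorders",F10
"Substance-related and addictive disorders",F11
"Substance-related and addictive disorders",F12
"Substance-related and addictive disorders",F13
"Substance-related and addictive disorders",F14
"Substance-related and addictive disorders",F15
"Substance-related and addictive disorders",F16
"Substance-related and addictive disorders",F17
"Substance-related and addictive disorders",F18
"Substance-related and addictive disorders",F19
"Somatic symptoms and related disorders",F45
"Schizophrenia spectrum and other psychotic disorders",F20
"Schizophrenia spectrum and other psychotic disorders",F21
"Schizophrenia spectrum and other psychotic disorders",F22
"Schizophrenia spectrum and other psychotic disorders",F23
"Schizophrenia spectrum and other psychotic disorders",F24
"Schizophrenia spectrum and other psychotic disorders",F25
"Schizophrenia spectrum and other psychotic disorders",F26
"Schizophrenia spectrum and other psychotic disorders",F27
"Schizophrenia spectrum and other psychotic disorders",F28
"Schizophrenia spectrum and other psychotic disorders",F29
"Obsessive-compulsive and related disorders",F42
"Bipolar and related disorders",F30
"Bipolar and related disorders",F31
"Sleep-wake disorders",F51
"Sleep-wake disorders",G47
"Personality disorders",F60
"Personality disorders",F61
"Personality disorders",F68
"Personality disorders",F69
"Dissociative disorders",F44
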