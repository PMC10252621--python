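{
 "variant": "cem",
 "oedema_criterion": "diffuse ipsilateral breast oedema",
 "tree": {
  "node": {
   "feature": "root_sign",
   "branches": {
    "present": {
     "node": {
      "feature": "oedema",
      "branches": {
       "absent": {
        "leaf": {
         "score": 8
        }
       },
       "present": {
        "leaf": {
         "score": 11
        }
       }
      }
     }
    },
    "absent": {
     "node": {
      "feature": "delayed_phase",
      "branches": {
       "persistent": {
        "node": {
         "feature": "margins",
         "branches": {
          "circumscribed": {
           "node": {
            "feature": "internal_enhancement",
            "branches": {
             "homogeneous_centrifugal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 1
                 }
                },
                "present": {
                 "leaf": {
                  "score": 5
                 }
                }
               }
              }
             },
             "inhomogeneous_centripetal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 3
                 }
                },
                "present": {
                 "leaf": {
                  "score": 7
                 }
                }
               }
              }
             }
            }
           }
          },
          "irregular": {
           "node": {
            "feature": "internal_enhancement",
            "branches": {
             "homogeneous_centrifugal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 3
                 }
                },
                "present": {
                 "leaf": {
                  "score": 7
                 }
                }
               }
              }
             },
             "inhomogeneous_centripetal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 5
                 }
                },
                "present": {
                 "leaf": {
                  "score": 9
                 }
                }
               }
              }
             }
            }
           }
          }
         }
        }
       },
       "plateau": {
        "node": {
         "feature": "margins",
         "branches": {
          "circumscribed": {
           "node": {
            "feature": "internal_enhancement",
            "branches": {
             "homogeneous_centrifugal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 2
                 }
                },
                "present": {
                 "leaf": {
                  "score": 6
                 }
                }
               }
              }
             },
             "inhomogeneous_centripetal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 4
                 }
                },
                "present": {
                 "leaf": {
                  "score": 8
                 }
                }
               }
              }
             }
            }
           }
          },
          "irregular": {
           "node": {
            "feature": "internal_enhancement",
            "branches": {
             "homogeneous_centrifugal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 4
                 }
                },
                "present": {
                 "leaf": {
                  "score": 8
                 }
                }
               }
              }
             },
             "inhomogeneous_centripetal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 6
                 }
                },
                "present": {
                 "leaf": {
                  "score": 10
                 }
                }
               }
              }
             }
            }
           }
          }
         }
        }
       },
       "washout": {
        "node": {
         "feature": "margins",
         "branches": {
          "circumscribed": {
           "node": {
            "feature": "internal_enhancement",
            "branches": {
             "homogeneous_centrifugal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 4
                 }
                },
                "present": {
                 "leaf": {
                  "score": 8
                 }
                }
               }
              }
             },
             "inhomogeneous_centripetal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 6
                 }
                },
                "present": {
                 "leaf": {
                  "score": 10
                 }
                }
               }
              }
             }
            }
           }
          },
          "irregular": {
           "node": {
            "feature": "internal_enhancement",
            "branches": {
             "homogeneous_centrifugal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 6
                 }
                },
                "present": {
                 "leaf": {
                  "score": 10
                 }
                }
               }
              }
             },
             "inhomogeneous_centripetal": {
              "node": {
               "feature": "oedema",
               "branches": {
                "absent": {
                 "leaf": {
                  "score": 8
                 }
                },
                "present": {
                 "leaf": {
                  "score": 12
                 }
                }
               }
              }
             }
            }
           }
          }
         }
        }
       }
      }
     }
    }
   }
  }
 }
}
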